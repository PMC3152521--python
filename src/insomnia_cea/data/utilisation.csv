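event_id,gp,spec_initial,spec_followup,psychologist,health_prac,alt_health_prac,rx,otc,transport
no_treatment,0,0,0,0,0,0,0,0,0
seek,0,0,0,0,0,0,0,0,0
1,0,0,0,0,0,0,0,1.0,1.0
1.1,1.0,0,0,0,0,0,1.0,0,1.0
1.2,0,0,0,0,0,0,0,0,0
2,1.0,0,0,0,0,0,0,0,1.0
2.1,0,0,0,0,0,0,0,0,0
2.2,0,0,0,0,0,0,1.0,0,0
2.2.1,0,0,0,0,0,0,0,0,0
2.2.2,0,0,0,0,0,0,0,0,0
2.2.2.1,0,0,0,4.0,0,0,0,0,4.0
2.2.2.2,0,1.0,1.0,0,0,0,1.0,0,2.0
2.2.2.3,0,0,0,0,2.0,0,0,0,2.0
3,0,0,0,0,1.0,0,0,0,1.0
3.1,0,0,0,0,0,0,0,0,0
3.2,0,0,0,0,0,0,0.5,0,0
3.2.1,0,0,0,0,0,0,0,0,0
3.2.2,0,0,0,0,0,0,0,0,0
3.2.2.1,0,0,0,4.0,0,0,0,0,4.0
3.2.2.2,0,1.0,1.0,0,0,0,1.0,0,2.0
3.2.2.3,1.0,0,0,0,0,0,1.0,0,1.0
3.2.2.4,0,0,0,0,3.0,0,0.5,0,3.0
4,0,0,0,1.0,0,0,0,0,1.0
4.1,0,0,0,0,0,0,0,0,0
4.2,0,0,0,0,0,0,0,0,0
4.2.1,0,0,0,0,0,0,0,0,0
4.2.2,0,0,0,0,0,0,0,0,0
4.2.2.1,0,0,0,4.0,0,0,0,0,4.0
4.2.2.2,0,1.0,1.0,0,0,0,1.0,0,2.0
4.2.2.3,1.0,0,0,0,0,0,1.0,0,1.0
4.2.2.4,0,0,0,0,0,0,0,0,0
5,0,0,0,0,0,1.0,0,0,1.0
5.1,0,0,0,0,0,0,0,0,0
5.2,0,0,0,0,0,2.0,0,0,2.0
5.2.2,0,0,0,0,0,0,0,0,0
5.2.3,0,0,0,0,0,0,0,0,0
5.2.3.1,0,0,0,0,0,2.0,0,0,2.0
5.2.3.2,1.0,0,0,0,0,0,0,0,1.0
5.2.3.3,0,0,0,0,0,0,0,0,0
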
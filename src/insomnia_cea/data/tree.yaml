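name: 'NZ insomnia treatment pathways [probabilities: synthetic]'
currency_year: 2009
root:
  id: root
  kind: chance
  p: 1.0
  children:
  - id: no_treatment
    kind: end
    p: 0.85
    event: no_treatment
  - id: seek
    kind: chance
    p: 0.15
    event: seek
    children:
    - id: '1'
      kind: chance
      p: 0.16500000000000004
      event: '1'
      children:
      - id: '1.1'
        kind: end
        p: 0.3
        event: '1.1'
      - id: '1.2'
        kind: end
        p: 0.7
        event: '1.2'
    - id: '2'
      kind: chance
      p: 0.4120000000000001
      event: '2'
      children:
      - id: '2.1'
        kind: end
        p: 0.2
        event: '2.1'
      - id: '2.2'
        kind: chance
        p: 0.8
        event: '2.2'
        children:
        - id: 2.2.1
          kind: end
          p: 0.7
          event: 2.2.1
        - id: 2.2.2
          kind: chance
          p: 0.3
          event: 2.2.2
          children:
          - id: 2.2.2.1
            kind: end
            p: 0.3333333333333333
            event: 2.2.2.1
          - id: 2.2.2.2
            kind: end
            p: 0.3333333333333333
            event: 2.2.2.2
          - id: 2.2.2.3
            kind: end
            p: 0.3333333333333333
            event: 2.2.2.3
    - id: '3'
      kind: chance
      p: 0.14100000000000001
      event: '3'
      children:
      - id: '3.1'
        kind: end
        p: 0.2
        event: '3.1'
      - id: '3.2'
        kind: chance
        p: 0.8
        event: '3.2'
        children:
        - id: 3.2.1
          kind: end
          p: 0.7
          event: 3.2.1
        - id: 3.2.2
          kind: chance
          p: 0.3
          event: 3.2.2
          children:
          - id: 3.2.2.1
            kind: end
            p: 0.25
            event: 3.2.2.1
          - id: 3.2.2.2
            kind: end
            p: 0.25
            event: 3.2.2.2
          - id: 3.2.2.3
            kind: end
            p: 0.25
            event: 3.2.2.3
          - id: 3.2.2.4
            kind: end
            p: 0.25
            event: 3.2.2.4
    - id: '4'
      kind: chance
      p: 0.07100000000000001
      event: '4'
      children:
      - id: '4.1'
        kind: end
        p: 0.2
        event: '4.1'
      - id: '4.2'
        kind: chance
        p: 0.8
        event: '4.2'
        children:
        - id: 4.2.1
          kind: end
          p: 0.7
          event: 4.2.1
        - id: 4.2.2
          kind: chance
          p: 0.3
          event: 4.2.2
          children:
          - id: 4.2.2.1
            kind: end
            p: 0.25
            event: 4.2.2.1
          - id: 4.2.2.2
            kind: end
            p: 0.25
            event: 4.2.2.2
          - id: 4.2.2.3
            kind: end
            p: 0.25
            event: 4.2.2.3
          - id: 4.2.2.4
            kind: end
            p: 0.25
            event: 4.2.2.4
    - id: '5'
      kind: chance
      p: 0.21100000000000002
      event: '5'
      children:
      - id: '5.1'
        kind: end
        p: 0.2
        event: '5.1'
      - id: '5.2'
        kind: chance
        p: 0.8
        event: '5.2'
        children:
        - id: 5.2.2
          kind: end
          p: 0.7
          event: 5.2.2
        - id: 5.2.3
          kind: chance
          p: 0.3
          event: 5.2.3
          children:
          - id: 5.2.3.1
            kind: end
            p: 0.3333333333333333
            event: 5.2.3.1
          - id: 5.2.3.2
            kind: end
            p: 0.3333333333333333
            event: 5.2.3.2
          - id: 5.2.3.3
            kind: end
            p: 0.3333333333333333
            event: 5.2.3.3
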
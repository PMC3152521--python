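"""The packaged New Zealand insomnia treatment model, plus synthetic inputs.

This module ships the model's published inputs as data files — unit
resource costs, the event × resource utilisation matrix, population and
health-cost parameters — together with the treatment-pathway tree topology:
five entry providers (pharmacist, GP, health practitioner, psychologist,
alternative health practitioner), each followed by no-further-action /
treat / refer branches, limited to one level of on-referral.

First-contact probabilities derive from a UK survey of where insomniacs
sought help, with nurse and counsellor grouped as "health practitioner",
and herbalist, acupuncturist and hypnotist grouped as "alternative health
practitioner"; psychiatrist has no entry branch in the model and is dropped
before renormalisation.

The downstream branch probabilities (success / refer splits and referral
destinations) were never published numerically. They are therefore
SYNTHETIC: plausible placeholder values carried with an explicit provenance
flag, plus a calibration helper that reverse-engineers a refer/success
split matching a target mean treatment cost. Calibrated values are a
consistency device, never ground truth.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import yaml

from .costing import UnitCostTable, UtilisationMatrix, build_event_costs
from .cua import PopulationScaling, evaluate
from .health_offsets import per_capita_cost, split_costs
from .sensitivity import SimulationSpec, TriangularParam, make_default_range
from .tree import (
    NodeKind,
    TreeModel,
    TreeNode,
    enumerate_pathways,
    expected_tree_cost,
    validate_tree,
)

__all__ = [
    "STINSON_FIRST_CONTACT_PERCENT",
    "ENTRY_NODE_FOR_PROVIDER",
    "SUCCESS_LEAVES",
    "FirstContactDistribution",
    "ProbabilityCompletion",
    "load_unit_costs",
    "load_utilisation",
    "load_parameters",
    "build_first_contact",
    "default_completion",
    "build_insomnia_tree",
    "expected_cost_per_treated",
    "branch_mean_costs",
    "benefit_share",
    "calibrate_refer_probability",
    "generate_random_tree",
    "default_psa_spec",
    "make_psa_model",
    "base_values",
]

_DATA = importlib.resources.files(__package__) / "data"

#: raw first-contact percentages from the UK treatment-seeking survey
STINSON_FIRST_CONTACT_PERCENT: dict[str, float] = {
    "pharmacist": 16.5,
    "general_practitioner": 41.2,
    "psychiatrist": 3.5,
    "psychologist": 7.1,
    "nurse": 3.5,
    "counsellor": 10.6,
    "herbalist": 8.2,
    "acupuncturist": 8.2,
    "hypnotist": 4.7,
}

_GROUPING = {
    "nurse": "health_practitioner",
    "counsellor": "health_practitioner",
    "herbalist": "alternative_health_practitioner",
    "acupuncturist": "alternative_health_practitioner",
    "hypnotist": "alternative_health_practitioner",
}
#: survey categories with no entry branch in the model
_DROPPED = ("psychiatrist",)

MODEL_PROVIDERS = (
    "pharmacist",
    "general_practitioner",
    "health_practitioner",
    "psychologist",
    "alternative_health_practitioner",
)

ENTRY_NODE_FOR_PROVIDER = {
    "pharmacist": "1",
    "general_practitioner": "2",
    "health_practitioner": "3",
    "psychologist": "4",
    "alternative_health_practitioner": "5",
}

# tree topology: chance node -> ordered children (node id == event id)
TOPOLOGY: dict[str, tuple[str, ...]] = {
    "seek": ("1", "2", "3", "4", "5"),
    "1": ("1.1", "1.2"),
    "2": ("2.1", "2.2"),
    "2.2": ("2.2.1", "2.2.2"),
    "2.2.2": ("2.2.2.1", "2.2.2.2", "2.2.2.3"),
    "3": ("3.1", "3.2"),
    "3.2": ("3.2.1", "3.2.2"),
    "3.2.2": ("3.2.2.1", "3.2.2.2", "3.2.2.3", "3.2.2.4"),
    "4": ("4.1", "4.2"),
    "4.2": ("4.2.1", "4.2.2"),
    "4.2.2": ("4.2.2.1", "4.2.2.2", "4.2.2.3", "4.2.2.4"),
    "5": ("5.1", "5.2"),
    "5.2": ("5.2.2", "5.2.3"),
    "5.2.3": ("5.2.3.1", "5.2.3.2", "5.2.3.3"),
}

#: leaves explicitly labelled "Success" in the pathway model
SUCCESS_LEAVES = frozenset({"1.2", "2.2.1", "3.2.1", "4.2.1", "5.2.2"})

#: treat-stage chance nodes whose refer/success split is synthetic
_TREAT_NODES = ("1", "2.2", "3.2", "4.2", "5.2")


@dataclass(frozen=True)
class FirstContactDistribution:
    """Probability of each entry provider being consulted first."""

    proportions: dict[str, float]

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"first-contact proportions sum to {total!r}")


@dataclass(frozen=True)
class ProbabilityCompletion:
    """Child branch probabilities for every chance node of the topology.

    ``provenance`` is ``"synthetic"`` whenever any downstream assignment is
    a placeholder rather than a published value; it propagates into every
    report built from the completion.
    """

    assignments: dict[str, dict[str, float]]
    provenance: str = "synthetic"

    def __post_init__(self):
        for node, probs in self.assignments.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"assignment for node {node!r} sums to {total!r}"
                )


def load_unit_costs() -> UnitCostTable:
    """The packaged unit resource cost table (NZD, GST-exclusive)."""
    with (_DATA / "unit_costs.csv").open() as fh:
        return UnitCostTable.from_csv(fh)


def load_utilisation() -> UtilisationMatrix:
    """The packaged event × resource utilisation matrix."""
    with (_DATA / "utilisation.csv").open() as fh:
        return UtilisationMatrix.from_csv(fh)


def load_parameters() -> dict:
    """The packaged population / health-cost / utility / PSA parameters."""
    with (_DATA / "parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


def build_first_contact(
    raw: Mapping[str, float] | None = None,
) -> FirstContactDistribution:
    """Group raw survey percentages into the model's five entry categories.

    Nurse and counsellor merge into ``health_practitioner``; herbalist,
    acupuncturist and hypnotist into ``alternative_health_practitioner``;
    psychiatrist is dropped. The survey allowed multiple consultations, so
    the grouped percentages are renormalised to sum to one.
    """
    if raw is None:
        raw = STINSON_FIRST_CONTACT_PERCENT
    grouped: dict[str, float] = {p: 0.0 for p in MODEL_PROVIDERS}
    for provider, pct in raw.items():
        if pct < 0:
            raise ValueError(f"negative percentage for {provider!r}")
        if provider in _DROPPED:
            continue
        grouped[_GROUPING.get(provider, provider)] += pct
    total = sum(grouped.values())
    if total == 0:
        raise ValueError("all first-contact percentages are zero")
    return FirstContactDistribution(
        proportions={p: v / total for p, v in grouped.items()}
    )


# Synthetic placeholder splits for the unpublished downstream probabilities:
# most patients respond to first-line care, a minority are referred on, and
# referral destinations are spread evenly over the available options.
_DEFAULT_TREAT_SPLIT = {"success": 0.7, "refer": 0.3}
_DEFAULT_NO_ACTION = 0.2  # P(no further action) at a provider consult


def default_completion(
    refer_probability: float = _DEFAULT_TREAT_SPLIT["refer"],
    first_contact: FirstContactDistribution | None = None,
) -> ProbabilityCompletion:
    """The packaged probability completion.

    First-contact proportions are survey-derived; every downstream split is
    synthetic (placeholder), so the completion's provenance is
    ``"synthetic"``. ``refer_probability`` sets P(refer) at each
    treat-stage node, shared by all five entry branches — the single knob
    the calibration helper turns.
    """
    if not 0.0 <= refer_probability <= 1.0:
        raise ValueError("refer probability outside [0, 1]")
    fc = first_contact if first_contact is not None else build_first_contact()
    success = 1.0 - refer_probability
    a: dict[str, dict[str, float]] = {
        "seek": {
            ENTRY_NODE_FOR_PROVIDER[p]: fc.proportions[p]
            for p in MODEL_PROVIDERS
        },
        # pharmacist: refer to GP vs success
        "1": {"1.1": refer_probability, "1.2": success},
    }
    for entry in ("2", "3", "4", "5"):
        no_action, treat = TOPOLOGY[entry]
        a[entry] = {no_action: _DEFAULT_NO_ACTION, treat: 1.0 - _DEFAULT_NO_ACTION}
        success_node, refer_node = TOPOLOGY[treat]
        a[treat] = {success_node: success, refer_node: refer_probability}
        dests = TOPOLOGY[refer_node]
        a[refer_node] = {d: 1.0 / len(dests) for d in dests}
    return ProbabilityCompletion(assignments=a, provenance="synthetic")


def build_insomnia_tree(
    completion: ProbabilityCompletion | None = None,
    p_seek: float = 0.15,
    seek_split_in_tree: bool = True,
) -> TreeModel:
    """Assemble the treatment-pathway tree from a probability completion.

    With ``seek_split_in_tree`` the root splits into a zero-cost
    "do not seek treatment" end node (probability ``1 − p_seek``) and the
    treatment subtree; otherwise the tree is conditional on seeking care
    and the seek node is the root. Raises ``KeyError`` naming any chance
    node the completion does not cover.
    """
    if completion is None:
        completion = default_completion()

    missing = [n for n in TOPOLOGY if n not in completion.assignments]
    if missing:
        raise KeyError(f"completion missing assignments for nodes: {missing}")

    def build(node_id: str, p: float) -> TreeNode:
        if node_id in TOPOLOGY:
            probs = completion.assignments[node_id]
            children = [
                build(child, probs[child]) for child in TOPOLOGY[node_id]
            ]
            return TreeNode(
                id=node_id,
                kind=NodeKind.CHANCE,
                branch_probability=p,
                event_id=node_id,
                children=children,
            )
        return TreeNode(
            id=node_id, kind=NodeKind.END, branch_probability=p, event_id=node_id
        )

    name = f"NZ insomnia treatment pathways [probabilities: {completion.provenance}]"
    seek = build("seek", p_seek if seek_split_in_tree else 1.0)
    if not seek_split_in_tree:
        return TreeModel(root=seek, name=name, currency_year=2009)
    root = TreeNode(
        id="root",
        kind=NodeKind.CHANCE,
        branch_probability=1.0,
        event_id=None,
        children=[
            TreeNode(
                id="no_treatment",
                kind=NodeKind.END,
                branch_probability=1.0 - p_seek,
                event_id="no_treatment",
            ),
            seek,
        ],
    )
    return TreeModel(root=root, name=name, currency_year=2009)


def expected_cost_per_treated(
    tree: TreeModel, event_costs: Mapping[str, float]
) -> float:
    """Mean treatment cost per person who seeks care.

    For a tree that carries the seek/no-seek split this conditions on the
    seek branch; for a conditional tree it is simply the expected tree cost.
    """
    if tree.root.id != "root":
        return expected_tree_cost(enumerate_pathways(tree, event_costs))
    seek = tree.find("seek")
    sub = TreeModel(
        root=TreeNode(
            id=seek.id,
            kind=seek.kind,
            branch_probability=1.0,
            event_id=seek.event_id,
            children=seek.children,
        ),
        name=tree.name,
        currency_year=tree.currency_year,
    )
    return expected_tree_cost(enumerate_pathways(sub, event_costs))


def branch_mean_costs(
    tree: TreeModel, event_costs: Mapping[str, float]
) -> dict[str, float]:
    """Mean treatment cost by entry provider (conditional on that entry)."""
    seek = tree.find("seek") if tree.root.id == "root" else tree.root
    out: dict[str, float] = {}
    for provider, node_id in ENTRY_NODE_FOR_PROVIDER.items():
        entry = next(c for c in seek.children if c.id == node_id)
        sub = TreeModel(
            root=TreeNode(
                id=entry.id,
                kind=entry.kind,
                branch_probability=1.0,
                event_id=entry.event_id,
                children=entry.children,
            )
        )
        out[provider] = expected_tree_cost(enumerate_pathways(sub, event_costs))
    return out


def benefit_share(tree: TreeModel, success_only: bool = False) -> float:
    """Probability mass of treated pathways eligible for the avoided-cost benefit.

    The base case treats every termination node of the treatment subtree as
    a successful outcome (share 1); ``success_only`` restricts the benefit
    to pathways ending at an explicit "Success" leaf.
    """
    if not success_only:
        return 1.0
    seek = tree.find("seek") if tree.root.id == "root" else tree.root
    sub = TreeModel(
        root=TreeNode(
            id=seek.id,
            kind=seek.kind,
            branch_probability=1.0,
            event_id=seek.event_id,
            children=seek.children,
        )
    )
    zero_costs = {n.event_id: 0.0 for n in sub.root.walk() if n.event_id}
    paths = enumerate_pathways(sub, zero_costs)  # probabilities only
    return sum(p.probability for p in paths if p.leaf in SUCCESS_LEAVES)


def calibrate_refer_probability(
    target_mean_cost: float,
    unit_costs: UnitCostTable | None = None,
    matrix: UtilisationMatrix | None = None,
    tol: float = 1e-6,
) -> float:
    """Reverse-engineer the shared refer probability matching a target mean.

    Finds, by bisection, the P(refer) under which the mean cost per person
    treated equals ``target_mean_cost``. The result is a calibrated
    placeholder — a value consistent with a published average, not a
    measurement of real referral behaviour.
    """
    costs = unit_costs if unit_costs is not None else load_unit_costs()
    mat = matrix if matrix is not None else load_utilisation()
    event_costs = build_event_costs(mat, costs)

    def mean_cost(refer_p: float) -> float:
        tree = build_insomnia_tree(
            default_completion(refer_probability=refer_p),
            seek_split_in_tree=False,
        )
        return expected_cost_per_treated(tree, event_costs)

    lo, hi = 0.0, 1.0
    f_lo, f_hi = mean_cost(lo), mean_cost(hi)
    if not f_lo <= target_mean_cost <= f_hi:
        raise ValueError(
            f"target {target_mean_cost} outside attainable range "
            f"[{f_lo:.2f}, {f_hi:.2f}]"
        )
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if mean_cost(mid) < target_mean_cost:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Random trees for property testing


def generate_random_tree(
    depth: int,
    max_branching: int = 4,
    seed: int = 0,
) -> tuple[TreeModel, dict[str, float]]:
    """A random valid tree with simplex branch probabilities and random costs.

    Depth 1 gives a single end node. Child probabilities are Dirichlet
    draws (so each sibling set sums to one exactly up to float rounding);
    event costs are uniform on [0, 100), with roughly one node in five a
    costless structural node. Reproducible under ``seed``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if max_branching < 1:
        raise ValueError("max_branching must be >= 1")
    rng = np.random.default_rng(seed)
    event_costs: dict[str, float] = {}
    counter = iter(range(10**9))

    def make(level: int, p: float) -> TreeNode:
        nid = f"n{next(counter)}"
        if rng.uniform() < 0.8:
            event_costs[nid] = float(rng.uniform(0.0, 100.0))
            event = nid
        else:
            event = None
        terminal = level >= depth or (level > 1 and rng.uniform() < 0.3)
        if terminal:
            return TreeNode(nid, NodeKind.END, p, event)
        k = int(rng.integers(2, max_branching + 1)) if max_branching >= 2 else 1
        probs = rng.dirichlet(np.ones(k))
        # renormalise away the last-bit float slack of the Dirichlet draw
        probs = probs / probs.sum()
        children = [make(level + 1, float(q)) for q in probs]
        return TreeNode(nid, NodeKind.CHANCE, p, event, children)

    root = make(1, 1.0)
    tree = TreeModel(root=root, name=f"random(depth={depth}, seed={seed})")
    return tree, event_costs


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis over the packaged model


def default_psa_spec(
    n_iterations: int = 10_000,
    seed: int = 0,
    fraction: float = 0.25,
    vary_costs: bool = True,
    vary_volumes: bool = True,
    vary_probabilities: bool = True,
    vary_population: bool = True,
    vary_utility: bool = True,
    unit_costs: UnitCostTable | None = None,
    matrix: UtilisationMatrix | None = None,
    completion: ProbabilityCompletion | None = None,
    parameters: Mapping | None = None,
) -> SimulationSpec:
    """Triangular ranges (base ±``fraction``) over every uncertain input.

    Covered inputs: unit resource costs, nonzero utilisation volumes,
    branch probabilities (renormalised per sibling set by the model
    closure), prevalence and treatment-seeking proportion, the
    insomniac cost increase (over its literature range 5–25%), and the
    QALY gain (its own low/base/high of 0 / 0.157 / 0.373). All inputs
    are sampled independently.
    """
    params_cfg = parameters if parameters is not None else load_parameters()
    costs = unit_costs if unit_costs is not None else load_unit_costs()
    mat = matrix if matrix is not None else load_utilisation()
    comp = completion if completion is not None else default_completion()

    params: list[TriangularParam] = []
    if vary_costs:
        for rid, res in costs.resources.items():
            params.append(
                make_default_range(res.unit_cost, fraction, target=f"cost:{rid}")
            )
    if vary_volumes:
        for (eid, rid), vol in sorted(mat.volumes.items()):
            params.append(
                make_default_range(vol, fraction, target=f"vol:{eid}:{rid}")
            )
    if vary_probabilities:
        for node in sorted(comp.assignments):
            for child, p in comp.assignments[node].items():
                if p > 0:
                    params.append(
                        make_default_range(p, fraction, target=f"p:{node}:{child}")
                    )
    pop = params_cfg["population"]
    if vary_population:
        # exactly-zero rates have a degenerate range; hold them fixed
        if pop["prevalence"] != 0:
            params.append(
                make_default_range(pop["prevalence"], fraction, target="prevalence")
            )
        if pop["p_seek"] != 0:
            params.append(
                make_default_range(pop["p_seek"], fraction, target="p_seek")
            )
        inc = params_cfg["health_costs"]
        params.append(
            TriangularParam(
                low=inc["cost_increase_range"][0],
                mode=inc["cost_increase"],
                high=inc["cost_increase_range"][1],
                target="cost_increase",
            )
        )
    if vary_utility:
        util = params_cfg["utility"]
        params.append(
            TriangularParam(
                low=util["low"], mode=util["base"], high=util["high"],
                target="qaly_gain",
            )
        )
    return SimulationSpec(params=params, n_iterations=n_iterations, seed=seed)


def make_psa_model(
    unit_costs: UnitCostTable | None = None,
    matrix: UtilisationMatrix | None = None,
    completion: ProbabilityCompletion | None = None,
    success_only: bool = False,
    parameters: Mapping | None = None,
) -> Callable[[Mapping[str, float]], dict[str, float]]:
    """Closure mapping one sampled parameter set to the three headline outputs.

    Outputs per iteration (all from the same sampled set):
    ``net_benefit_per_person`` ($), ``net_benefit_total_millions`` ($M
    nationally), ``net_benefit_per_qaly`` ($/QALY). Any target absent from
    the sampled mapping stays at its base-case value, so a spec varying
    only a subset of inputs leaves the rest fixed. Sibling branch
    probabilities are renormalised after sampling; a sampled set yielding
    an invalid tree raises ``ValueError`` (counted by the Monte Carlo
    driver).
    """
    costs = unit_costs if unit_costs is not None else load_unit_costs()
    mat = matrix if matrix is not None else load_utilisation()
    comp = completion if completion is not None else default_completion()
    params_cfg = parameters if parameters is not None else load_parameters()
    pop = params_cfg["population"]
    hc = params_cfg["health_costs"]
    util = params_cfg["utility"]
    tp = per_capita_cost(
        hc["personal_medical_services_millions"], hc["population_millions"]
    )

    # static pathway skeleton of the treatment subtree: for each leaf, the
    # chance-node edges taken and the events incurred
    skeleton: list[tuple[str, tuple[tuple[str, str], ...], tuple[str, ...]]] = []

    def walk(node_id: str, edges: tuple, events: tuple) -> None:
        events = events + (node_id,)
        if node_id not in TOPOLOGY:
            skeleton.append((node_id, edges, events))
            return
        for child in TOPOLOGY[node_id]:
            walk(child, edges + ((node_id, child),), events)

    walk("seek", (), ())

    base_share = 1.0
    if success_only:
        base_share = benefit_share(build_insomnia_tree(comp), success_only=True)

    def model(drawn: Mapping[str, float]) -> dict[str, float]:
        def get(key: str, base: float) -> float:
            return float(drawn.get(key, base))

        ucost = {
            rid: get(f"cost:{rid}", res.unit_cost)
            for rid, res in costs.resources.items()
        }
        event_cost: dict[str, float] = {}
        for (eid, rid), vol in mat.volumes.items():
            v = get(f"vol:{eid}:{rid}", vol)
            event_cost[eid] = event_cost.get(eid, 0.0) + v * ucost[rid]

        edge_p: dict[tuple[str, str], float] = {}
        for node, probs in comp.assignments.items():
            sampled = {
                child: get(f"p:{node}:{child}", p) for child, p in probs.items()
            }
            total = sum(sampled.values())
            if total <= 0 or any(v < 0 for v in sampled.values()):
                raise ValueError(f"invalid sampled probabilities at node {node!r}")
            for child, v in sampled.items():
                edge_p[(node, child)] = v / total

        cost_per_treated = 0.0
        success_mass = 0.0
        for leaf, edges, events in skeleton:
            p = 1.0
            for e in edges:
                p *= edge_p[e]
            c = sum(event_cost.get(ev, 0.0) for ev in events)
            cost_per_treated += p * c
            if leaf in SUCCESS_LEAVES:
                success_mass += p

        prevalence = get("prevalence", pop["prevalence"])
        p_seek = get("p_seek", pop["p_seek"])
        increase = get("cost_increase", hc["cost_increase"])
        qaly = get("qaly_gain", util["base"])
        share = success_mass if success_only else 1.0
        delta = split_costs(tp, prevalence, 1.0 + increase).delta * share
        result = evaluate(
            cost_per_person=cost_per_treated,
            avoided_per_person=delta,
            qaly_gain=qaly,
            scaling=PopulationScaling(pop["at_risk_millions"], prevalence, p_seek),
        )
        return {
            "net_benefit_per_person": result.net_benefit_per_person,
            "net_benefit_total_millions": result.total_net_benefit,
            "net_benefit_per_qaly": result.cost_per_qaly,
        }

    model.base_share = base_share  # type: ignore[attr-defined]
    return model


def base_values(spec: SimulationSpec) -> dict[str, float]:
    """The degenerate draw {target: mode}; running the model on it gives the
    deterministic base case."""
    return {p.target: p.mode for p in spec.params}
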
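"""Ground-truth synthetic data with the statistical structure the pipeline assumes.

The generator emulates the root-hair regulatory setting: a small set of
transcription factors (two trihelix repressors, GTL1 and DF1, and one bHLH
activator, RSL4) regulating a few dozen shared target genes, profiled across
knockout/overexpression genotypes, plus a short developmental time course and
a noisy direct-binding (ChIP-like) pair set.  Everything is reproducible
bit-for-bit from an integer seed.

Design notes
------------
* Baseline expression is 100 arbitrary units for every gene; downstream
  methods are scale-free.
* Replicate noise is multiplicative log-normal with a given coefficient of
  variation; microarray-style noise structure is not modelled beyond that.
* Knockouts zero the perturbed gene's own row; for propagation to targets the
  missing protein is represented by a small residual relative level
  (``ko_residual``), so targets of a knocked-out repressor rise above
  baseline (de-repression) and targets of a knocked-out activator fall.
* The time-course generator is built so the lag-1 sign rule is an exact
  oracle: regulators receive randomized kicks on even transitions
  (round-robin), every direct target responds exactly one transition later,
  and responses do not propagate further.  See docs/methods.md for the
  argument that this yields uncontaminated majority votes for every edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import (BindingSet, ExpressionMatrix, GroundTruthNetwork,
                         TimeCourse, TrueEdge)
from .errors import InvalidArgument

import pandas as pd

BASELINE = 100.0
DEFAULT_REGULATORS = ("GTL1", "DF1", "RSL4")
DEFAULT_REPRESSORS = ("GTL1", "DF1")
KO_RESIDUAL = 0.1


@dataclass(frozen=True)
class GenotypeSpec:
    """A named genotype as a map gene -> expression multiplier.

    Multiplier 0 encodes a null (knockout) allele, values > 1 encode
    overexpression; the wild type is the empty map.
    """

    name: str
    perturbations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, mult in self.perturbations.items():
            if not np.isfinite(mult) or mult < 0:
                raise InvalidArgument(
                    f"genotype {self.name!r}: multiplier for {gene!r} must be "
                    f"a finite value >= 0, got {mult}")


def default_genotypes() -> list[GenotypeSpec]:
    """The six-genotype perturbation design: wild type, two single knockouts,
    the double knockout, and 15x / 30x trichoblast-driven overexpression."""
    return [
        GenotypeSpec("wt", {}),
        GenotypeSpec("gtl1", {"GTL1": 0.0}),
        GenotypeSpec("df1", {"DF1": 0.0}),
        GenotypeSpec("gtl1_df1", {"GTL1": 0.0, "DF1": 0.0}),
        GenotypeSpec("GTL1ox", {"GTL1": 15.0}),
        GenotypeSpec("DF1ox", {"DF1": 30.0}),
    ]


def make_ground_truth_network(
    n_targets: int,
    regulators: Sequence[str] = DEFAULT_REGULATORS,
    edge_density: float = 0.15,
    include_feedback: bool = True,
    seed: int = 0,
    repressors: Sequence[str] = DEFAULT_REPRESSORS,
    autoregulation: bool = False,
) -> GroundTruthNetwork:
    """Draw a signed regulator->target network.

    Each (regulator, target) pair becomes an edge with probability
    ``edge_density``; effect-size magnitudes are Uniform[0.5, 2] and the sign
    follows the regulator's configured role (repressors negative, others
    positive).  With ``include_feedback`` the first activator/repressor pair
    get a mutual activator->repressor(+) / repressor->activator(-) edge pair,
    the motif of a negative-feedback loop; ``autoregulation`` additionally
    adds a self-repression edge on the repressor.
    """
    if n_targets < 0:
        raise InvalidArgument(f"n_targets must be >= 0, got {n_targets}")
    if not regulators:
        raise InvalidArgument("regulator set must be nonempty")
    if not 0 < edge_density <= 1:
        raise InvalidArgument(f"edge_density must be in (0, 1], got {edge_density}")
    regulators = [str(r) for r in regulators]
    targets = [f"T{i+1:02d}" for i in range(n_targets)]
    overlap = set(regulators) & set(targets)
    if len(set(regulators)) != len(regulators) or overlap:
        raise InvalidArgument("duplicate gene ids in regulators/targets")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E6574]))
    repset = {r for r in repressors if r in regulators}
    edges: list[TrueEdge] = []
    for reg in regulators:
        role = -1.0 if reg in repset else 1.0
        keep = rng.random(n_targets) < edge_density
        mags = rng.uniform(0.5, 2.0, size=n_targets)
        for t, k, m in zip(targets, keep, mags):
            if k:
                edges.append(TrueEdge(reg, t, role * m))

    if include_feedback:
        activators = [r for r in regulators if r not in repset]
        reps = [r for r in regulators if r in repset]
        if not activators or not reps:
            raise InvalidArgument(
                "include_feedback needs at least one activator and one repressor")
        act, rep = activators[0], reps[0]
        edges.append(TrueEdge(act, rep, rng.uniform(0.5, 2.0)))
        edges.append(TrueEdge(rep, act, -rng.uniform(0.5, 2.0)))
        if autoregulation:
            edges.append(TrueEdge(rep, rep, -rng.uniform(0.5, 2.0)))

    return GroundTruthNetwork(regulators=regulators, targets=targets,
                              edges=edges, seed=int(seed))


# ---------------------------------------------------------------------------
# genotype perturbation expression
# ---------------------------------------------------------------------------

def _propagate_means(net: GroundTruthNetwork,
                     genotype: GenotypeSpec,
                     ko_residual: float = KO_RESIDUAL) -> np.ndarray:
    """Deterministic steady-state mean expression for one genotype.

    Regulator protein levels (relative to baseline) are set by the genotype's
    multipliers; each gene with incoming edges gets
    ``baseline * prod(rel_level ** effect_size)``.  A knockout contributes a
    residual relative level ``ko_residual`` to its outgoing edges (no
    functional protein), while its own transcript row is exactly 0.
    """
    nodes = net.nodes
    nodeset = set(nodes)
    for gene in genotype.perturbations:
        if gene not in nodeset:
            raise InvalidArgument(
                f"genotype {genotype.name!r} perturbs {gene!r}, which is not "
                f"in the network")
    rel = {g: 1.0 for g in nodes}
    for gene, mult in genotype.perturbations.items():
        rel[gene] = float(mult)

    incoming: dict[str, list[TrueEdge]] = {g: [] for g in nodes}
    for e in net.edges:
        incoming[e.target].append(e)

    means = np.empty(len(nodes))
    for i, gene in enumerate(nodes):
        mult = genotype.perturbations.get(gene)
        level = BASELINE
        for e in incoming[gene]:
            if e.regulator == gene:
                continue  # self-edges do not feed back into the one-step mean
            r = rel[e.regulator]
            if r == 0.0:
                r = ko_residual
            level *= r ** e.effect_size
        if mult is not None:
            # a genotype lesion on the gene itself overrides regulation
            level = BASELINE * mult
        means[i] = level
    return means


def simulate_genotype_expression(
    net: GroundTruthNetwork,
    genotypes: Sequence[GenotypeSpec] | None = None,
    n_reps: int = 3,
    noise_cv: float = 0.2,
    seed: int = 0,
    ko_residual: float = KO_RESIDUAL,
) -> ExpressionMatrix:
    """Simulate a replicated perturbation-genotype expression matrix.

    Each replicate draws one log-normal fluctuation factor per gene
    (coefficient of variation ``noise_cv``; noise_cv = 0 gives identical
    replicate columns).  A regulator's fluctuation is shared between its own
    measured row and the response of its targets in the same replicate —
    target expression is a per-sample function of realized regulator levels,
    which is exactly the dependence structure regression-based network
    inference assumes.  A knocked-out regulator has no protein, hence no
    fluctuation to propagate: its outgoing influence is the fixed residual
    level.
    """
    if genotypes is None:
        genotypes = default_genotypes()
    if n_reps < 1:
        raise InvalidArgument(f"n_reps must be >= 1, got {n_reps}")
    if noise_cv < 0:
        raise InvalidArgument(f"noise_cv must be >= 0, got {noise_cv}")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x65787072]))
    nodes = net.nodes
    node_idx = {g: i for i, g in enumerate(nodes)}
    incoming: dict[str, list[TrueEdge]] = {g: [] for g in nodes}
    for e in net.edges:
        if e.regulator != e.target:
            incoming[e.target].append(e)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    # log-normal with E[factor] = 1 and CV = noise_cv
    sigma2 = float(np.log1p(noise_cv ** 2))
    sigma = float(np.sqrt(sigma2))
    for gt in genotypes:
        means = _propagate_means(net, gt, ko_residual=ko_residual)
        for rep in range(1, n_reps + 1):
            if noise_cv > 0:
                factors = rng.lognormal(mean=-sigma2 / 2, sigma=sigma,
                                        size=len(nodes))
            else:
                factors = np.ones(len(nodes))
            # realized regulatory level of each regulator, relative to
            # baseline, in this replicate (0-mean regulators sit at the
            # un-fluctuating knockout residual)
            rel = {}
            for reg in net.regulators:
                m = means[node_idx[reg]]
                rel[reg] = (m / BASELINE) * factors[node_idx[reg]] \
                    if m > 0 else ko_residual
            values = np.empty(len(nodes))
            for i, gene in enumerate(nodes):
                if gene in net.regulators or gene in gt.perturbations \
                        or not incoming[gene]:
                    values[i] = means[i] * factors[i]
                else:
                    level = BASELINE
                    for e in incoming[gene]:
                        r = rel[e.regulator]
                        level *= r ** e.effect_size
                    values[i] = level * factors[i]
            sid = f"{gt.name}_r{rep}"
            cols[sid] = values
            meta_rows.append((sid, gt.name, rep, "", ""))

    values = pd.DataFrame(cols, index=pd.Index(nodes, name="gene_id"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "genotype",
                                            "replicate", "timepoint", "zone"]
                        ).set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta)


# ---------------------------------------------------------------------------
# time course
# ---------------------------------------------------------------------------

def simulate_time_course(
    net: GroundTruthNetwork,
    timepoints: int = 5,
    zones: int = 2,
    lag_model: str = "first-order-lag",
    seed: int = 0,
    timepoint_labels: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Simulate an ordered (zone x timepoint) expression series.

    Regulators receive randomized multiplicative kicks on even transitions,
    one regulator per transition (round-robin, offset by zone); every direct
    target responds with the edge's signed effect exactly one transition
    later, and responses do not propagate further.  This makes the lag-1
    majority-vote sign rule an exact oracle on noise-free output for every
    regulator->target and feedback edge (self-loops excluded).

    Raises if some regulator would get no scorable kick (increase
    ``timepoints`` or ``zones``).
    """
    if timepoints < 3:
        raise InvalidArgument(
            f"timepoints must be >= 3 for the lag-1 sign rule, got {timepoints}")
    if zones < 1:
        raise InvalidArgument(f"zones must be >= 1, got {zones}")
    if lag_model != "first-order-lag":
        raise InvalidArgument(f"unknown lag_model {lag_model!r}")

    nodes = net.nodes
    n_reg = len(net.regulators)
    n_trans = timepoints - 1
    # a kick at transition k is scorable iff the response transition k+1 exists
    scorable_kick_slots = [k for k in range(0, n_trans - 1, 2)]
    covered = set()
    for z in range(zones):
        for j, k in enumerate(scorable_kick_slots):
            covered.add((j + z) % n_reg)
    if len(covered) < n_reg:
        raise InvalidArgument(
            f"{n_reg} regulators cannot all be exercised with "
            f"{timepoints} timepoints and {zones} zone(s); "
            f"increase timepoints or zones")

    incoming: dict[str, list[TrueEdge]] = {g: [] for g in nodes}
    for e in net.edges:
        if e.regulator != e.target:
            incoming[e.target].append(e)

    if timepoint_labels is None:
        timepoint_labels = [f"t{i+1}" for i in range(timepoints)]
    elif len(timepoint_labels) != timepoints:
        raise InvalidArgument("timepoint_labels length must equal timepoints")

    gene_index = {g: i for i, g in enumerate(nodes)}
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for z in range(zones):
        # zone streams are seeded independently so zone 1 is identical
        # whether one or many zones are requested
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), 0x74630000 + z]))
        logx = np.zeros((len(nodes), timepoints))  # log(level/baseline)
        kick_at: dict[int, tuple[int, float]] = {}
        for j, k in enumerate(scorable_kick_slots):
            reg_idx = (j + z) % n_reg
            mag = rng.uniform(0.2, 0.5)
            kick = mag * (1.0 if rng.random() < 0.5 else -1.0)
            kick_at[k] = (reg_idx, kick)
        for t in range(1, timepoints):
            logx[:, t] = logx[:, t - 1]
            k = t - 1  # transition index leading into timepoint t
            if k in kick_at:
                reg_idx, kick = kick_at[k]
                logx[gene_index[nodes[reg_idx]], t] += kick
            prev = k - 1
            if prev in kick_at:
                reg_idx, kick = kick_at[prev]
                mover = nodes[reg_idx]
                for gene in nodes:
                    for e in incoming[gene]:
                        if e.regulator == mover:
                            logx[gene_index[gene], t] += e.effect_size * kick
        levels = BASELINE * np.exp(logx)
        zone_label = f"z{z+1}"
        for t, tl in enumerate(timepoint_labels):
            sid = f"{zone_label}_{tl}"
            cols[sid] = levels[:, t]
            meta_rows.append((sid, "wt", 1, tl, zone_label))

    values = pd.DataFrame(cols, index=pd.Index(nodes, name="gene_id"))
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "genotype",
                                            "replicate", "timepoint", "zone"]
                        ).set_index("sample_id")
    return ExpressionMatrix(values=values, sample_meta=meta)


def time_course_from_expression(expr: ExpressionMatrix) -> TimeCourse:
    """Convenience: reshape a time-course-layout expression matrix."""
    return TimeCourse.from_expression(expr)


# ---------------------------------------------------------------------------
# binding set
# ---------------------------------------------------------------------------

def make_binding_set(net: GroundTruthNetwork, tpr: float = 1.0,
                     fpr: float = 0.0, seed: int = 0) -> BindingSet:
    """Corrupt the true edge set into ChIP-like binding evidence.

    Every true (regulator, target) edge is retained with probability ``tpr``;
    every candidate non-edge pair is spuriously included with probability
    ``fpr``.
    """
    if not 0 <= tpr <= 1:
        raise InvalidArgument(f"tpr must be in [0, 1], got {tpr}")
    if not 0 <= fpr <= 1:
        raise InvalidArgument(f"fpr must be in [0, 1], got {fpr}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x62696E64]))
    true_pairs = net.edge_pairs()
    pairs = set()
    for reg in net.regulators:
        for tgt in net.nodes:
            if reg == tgt:
                continue
            p = tpr if (reg, tgt) in true_pairs else fpr
            if rng.random() < p:
                pairs.add((reg, tgt))
    return BindingSet(pairs=frozenset(pairs))
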
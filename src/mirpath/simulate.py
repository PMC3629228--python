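"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators emulate the data shapes of a paired qPCR miRNA screen
across six cell lines, a multi-algorithm target-prediction compendium,
and MSigDB-style gene-set collections:

* ``simulate_profiles`` — paired ΔCt profiles with planted ≥2-fold
  differentially expressed miRNAs (DEmiRs), spurious per-line DE among
  the nulls, Gaussian cycle noise and missing readouts.  It also assigns
  the ground-truth miRNA→gene target map, including a pool of "hub"
  genes co-targeted by several planted up-regulated DEmiRs (the pathway
  co-targeting structure the enrichment stage is designed to detect).
* ``simulate_scores`` — per-algorithm prediction scores drawn from
  class-conditional gamma distributions with per-algorithm dropout,
  split into a labelled training set and an unlabelled candidate pool.
* ``simulate_gene_sets`` — background sets drawn uniformly from the
  gene universe plus planted sets whose members are preferentially the
  co-targeted hub genes.

All three are deterministic given ``SimulationConfig.seed`` (independent
child streams per generator), so identical seeds reproduce byte-identical
output files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .differential import PairedProfile
from .targets import DEFAULT_ALGORITHMS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "GeneSets",
    "ScoreSimulation",
    "simulate_profiles",
    "simulate_scores",
    "simulate_gene_sets",
]

_PROFILE_STREAM, _SCORE_STREAM, _GENESET_STREAM = 1, 2, 3


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults emulate the screen geometry: ~750 assayed miRNAs across 6
    paired cell-line profiles, 30 planted DEmiRs with 1.2–2.5 log2-fold
    effects, 20% spurious per-line DE among nulls, 0.3-cycle noise, 5%
    missing readouts, six prediction algorithms with gamma class score
    distributions, a 929:23,319 positive:negative training split, and
    gene sets of 20–60 members over a 20,000-gene universe with planted
    sets at 25% true-target coverage.
    """

    seed: int = 0
    # expression screen
    n_mirnas: int = 750
    n_cell_lines: int = 6
    n_planted_demirs: int = 30
    fraction_up: float = 0.8
    effect_low: float = 1.2     # |log2 fold change| of planted effects
    effect_high: float = 2.5
    per_line_de_prob: float = 0.2   # spurious DE rate per null miRNA per line
    planted_line_prob: float = 0.9  # per-line DE rate for planted miRNAs ...
    signature_min_lines: int = 4    # ... redrawn until >= this many lines
    missing_rate: float = 0.05      # per (miRNA, cell line), both fractions
    missing_not_at_random: bool = False
    noise_sd: float = 0.3           # ΔCt cycles
    baseline_ct: float = 6.0
    baseline_sd: float = 2.5
    fold_threshold: float = 2.0
    # target map
    n_genes: int = 20_000
    targets_per_demir: int = 38
    cotargeting: int = 3            # up-DEmiRs per hub gene
    validated_fraction: float = 0.05
    # prediction scores
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS
    gamma_pos: tuple[float, float] = (3.0, 2.0)   # shape, scale for y=1
    gamma_neg: tuple[float, float] = (1.0, 1.0)
    detect_rate_pos: float = 0.85
    detect_rate_neg: float = 0.5
    n_pos_training: int = 929
    n_neg_training: int = 23_319
    false_candidates_per_mirna: int = 380
    # gene sets
    n_background_sets: int = 50
    n_planted_sets: int = 5
    planted_coverage: float = 0.25
    set_size_min: int = 20
    set_size_max: int = 60

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_cell_lines, self.n_genes,
               self.n_planted_demirs, self.targets_per_demir) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_planted_demirs > self.n_mirnas:
            raise ValueError("cannot plant more DEmiRs than miRNAs")
        for name in ("fraction_up", "per_line_de_prob", "planted_line_prob",
                     "missing_rate", "validated_fraction", "planted_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_low > self.effect_high or self.effect_low <= 0:
            raise ValueError("effect range must satisfy 0 < low <= high")
        if self.signature_min_lines > self.n_cell_lines:
            raise ValueError("signature_min_lines exceeds the cell line count")
        for pair in (self.gamma_pos, self.gamma_neg):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("gamma shape and scale must be positive")
        if self.set_size_min > self.set_size_max or self.set_size_min <= 0:
            raise ValueError("invalid gene-set size range")

    # id vocabularies (deterministic, rng-free)
    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(1, self.n_mirnas + 1)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(1, self.n_genes + 1)]

    @property
    def cell_line_ids(self) -> list[str]:
        return [f"CL{j}" for j in range(1, self.n_cell_lines + 1)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class GroundTruth:
    """What was planted: DEmiRs, the target map and the enriched sets."""

    planted_demirs: list[str]
    directions: dict[str, int]            # +1 up, -1 down
    de_lines: dict[str, list[int]]        # cell-line indices carrying the effect
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    hub_genes: list[str] = field(default_factory=list)
    validated_pairs: set[tuple[str, str]] = field(default_factory=set)
    planted_sets: list[str] = field(default_factory=list)

    def targets_of(self, mirna_id: str) -> list[str]:
        return sorted(g for (m, g) in self.true_pairs if m == mirna_id)

    def to_json(self, path) -> None:
        payload = {
            "planted_demirs": self.planted_demirs,
            "directions": self.directions,
            "de_lines": self.de_lines,
            "true_pairs": sorted(self.true_pairs),
            "hub_genes": self.hub_genes,
            "validated_pairs": sorted(self.validated_pairs),
            "planted_sets": self.planted_sets,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _assign_targets(
    config: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> None:
    """Build the true miRNA→gene map, with co-targeted hub genes.

    A pool of hub genes (enough to fill every planted set at the
    configured coverage) is created first; each hub is assigned as a true
    target of ``cotargeting`` distinct planted up-regulated DEmiRs, the
    co-targeting that later concentrates regulation on planted sets.  The
    remaining target slots of every planted DEmiR are filled with genes
    drawn outside the hub pool.  Null miRNAs carry no true targets.
    """
    genes = config.gene_ids
    up = [m for m in truth.planted_demirs if truth.directions[m] == 1]
    hub_per_set = math.ceil(config.planted_coverage * config.set_size_max)
    n_hubs = config.n_planted_sets * hub_per_set
    cot = min(config.cotargeting, len(up)) if up else 0
    if config.n_planted_sets > 0:
        if not up:
            raise ValueError("planted gene sets need at least one up-regulated DEmiR")
        if n_hubs * cot > len(up) * config.targets_per_demir:
            raise ValueError(
                "requested planted coverage unattainable: "
                f"{n_hubs} hub genes x {cot} co-targeting slots exceed "
                f"{len(up)} up-DEmiRs x {config.targets_per_demir} target slots"
            )
    hub_idx = rng.choice(config.n_genes, size=n_hubs, replace=False)
    truth.hub_genes = [genes[i] for i in hub_idx]
    capacity = {m: config.targets_per_demir for m in truth.planted_demirs}
    for hub in truth.hub_genes:
        open_up = [m for m in up if capacity[m] > 0]
        chosen = rng.choice(len(open_up), size=cot, replace=False)
        for ci in chosen:
            m = open_up[ci]
            truth.true_pairs.add((m, hub))
            capacity[m] -= 1
    hub_set = set(hub_idx.tolist())
    non_hub = np.array([i for i in range(config.n_genes) if i not in hub_set])
    for m in truth.planted_demirs:
        extra = rng.choice(len(non_hub), size=capacity[m], replace=False)
        for gi in non_hub[extra]:
            truth.true_pairs.add((m, genes[gi]))
    if config.validated_fraction > 0 and truth.true_pairs:
        pairs = sorted(truth.true_pairs)
        n_val = int(round(config.validated_fraction * len(pairs)))
        picked = rng.choice(len(pairs), size=n_val, replace=False)
        truth.validated_pairs = {pairs[i] for i in sorted(picked)}


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[list[PairedProfile], GroundTruth]:
    """Generate paired ΔCt profiles and the full ground truth.

    Reference ΔCt is Normal(baseline, spread) per (miRNA, line).  The
    test fraction subtracts direction × effect on the DE lines (planted
    miRNAs carry the effect on a consistent ≥4-of-6 subset of lines; null
    miRNAs receive independent spurious effects per line at the null DE
    rate) and adds Normal(0, noise_sd) everywhere.  Missingness removes
    the readout of both fractions of a cell, at random by default or
    preferentially for low-expressed cells when ``missing_not_at_random``.
    """
    rng = config.rng(_PROFILE_STREAM)
    I, J = config.n_mirnas, config.n_cell_lines
    mirnas = config.mirna_ids

    planted_idx = np.sort(rng.choice(I, size=config.n_planted_demirs, replace=False))
    directions = np.where(
        rng.random(config.n_planted_demirs) < config.fraction_up, 1, -1
    )
    effects = rng.uniform(config.effect_low, config.effect_high,
                          size=config.n_planted_demirs)

    effect_matrix = np.zeros((I, J))
    de_lines: dict[str, list[int]] = {}
    for p, (i, d, e) in enumerate(zip(planted_idx, directions, effects)):
        while True:
            lines = rng.random(J) < config.planted_line_prob
            if lines.sum() >= config.signature_min_lines:
                break
        effect_matrix[i, lines] = d * e
        de_lines[mirnas[i]] = np.flatnonzero(lines).tolist()

    null_mask = np.ones(I, dtype=bool)
    null_mask[planted_idx] = False
    spur = (rng.random((I, J)) < config.per_line_de_prob) & null_mask[:, None]
    spur_effects = rng.uniform(config.effect_low, config.effect_high, size=(I, J))
    spur_signs = rng.choice([-1.0, 1.0], size=(I, J))
    effect_matrix[spur] = (spur_effects * spur_signs)[spur]

    reference = rng.normal(config.baseline_ct, config.baseline_sd, size=(I, J))
    noise = (rng.normal(0.0, config.noise_sd, size=(I, J))
             if config.noise_sd > 0 else np.zeros((I, J)))
    test = reference - effect_matrix + noise

    if config.missing_rate > 0:
        if config.missing_not_at_random:
            # drop the least-expressed cells (highest ΔCt = latest amplification)
            mean_ct = (test + reference) / 2.0
            cut = np.quantile(mean_ct, 1.0 - config.missing_rate)
            miss = mean_ct > cut
        else:
            miss = rng.random((I, J)) < config.missing_rate
    else:
        miss = np.zeros((I, J), dtype=bool)
    test = np.where(miss, np.nan, test)
    reference = np.where(miss, np.nan, reference)

    profiles = [
        PairedProfile(cl, mirnas, test[:, j], reference[:, j])
        for j, cl in enumerate(config.cell_line_ids)
    ]
    truth = GroundTruth(
        planted_demirs=[mirnas[i] for i in planted_idx],
        directions={mirnas[i]: int(d) for i, d in zip(planted_idx, directions)},
        de_lines=de_lines,
    )
    _assign_targets(config, truth, rng)
    return profiles, truth


@dataclass
class ScoreSimulation:
    """Labelled training scores plus an unlabelled candidate pool.

    ``candidate_labels`` is held alongside (not inside) the candidate
    frame: it is evaluation ground truth, invisible to the pipeline.
    """

    training: pd.DataFrame        # algorithm columns + 'label'
    candidates: pd.DataFrame      # mirna_id, gene_id, algorithm columns
    candidate_labels: np.ndarray

    def write_training_tsv(self, path) -> None:
        self.training.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def write_candidates_tsv(self, path) -> None:
        self.candidates.to_csv(path, sep="\t", index=False, float_format="%.6f")


def _draw_scores(
    rng: np.random.Generator,
    n: int,
    config: SimulationConfig,
    positive: bool,
) -> np.ndarray:
    shape, scale = config.gamma_pos if positive else config.gamma_neg
    rate = config.detect_rate_pos if positive else config.detect_rate_neg
    A = len(config.algorithms)
    X = rng.gamma(shape, scale, size=(n, A))
    drop = rng.random((n, A)) >= rate
    # keep every pair scored by at least one algorithm
    all_dropped = drop.all(axis=1)
    if all_dropped.any():
        keep = rng.integers(0, A, size=int(all_dropped.sum()))
        drop[np.flatnonzero(all_dropped), keep] = False
    X[drop] = np.nan
    return X


def simulate_scores(
    config: SimulationConfig,
    truth: GroundTruth,
    mirna_ids: list[str] | None = None,
) -> ScoreSimulation:
    """Generate training and candidate prediction scores.

    True pairs draw from the positive-class gammas, false pairs from the
    negative class, each with per-algorithm dropout.  The candidate pool
    covers, for each queried miRNA (default: the planted DEmiRs), its
    true targets plus ``false_candidates_per_mirna`` random non-target
    genes; null miRNAs contribute only false candidates.
    """
    if not truth.true_pairs:
        raise ValueError("ground truth carries no true pairs; run simulate_profiles")
    rng = config.rng(_SCORE_STREAM)
    algs = list(config.algorithms)

    Xp = _draw_scores(rng, config.n_pos_training, config, positive=True)
    Xn = _draw_scores(rng, config.n_neg_training, config, positive=False)
    training = pd.DataFrame(np.vstack([Xp, Xn]), columns=algs)
    training["label"] = np.concatenate(
        [np.ones(config.n_pos_training, dtype=int),
         np.zeros(config.n_neg_training, dtype=int)]
    )

    queries = list(mirna_ids) if mirna_ids is not None else list(truth.planted_demirs)
    genes = config.gene_ids
    rows_m, rows_g, labels = [], [], []
    for m in queries:
        true_targets = truth.targets_of(m)
        rows_m += [m] * len(true_targets)
        rows_g += true_targets
        labels += [1] * len(true_targets)
        excluded = set(true_targets)
        n_false = config.false_candidates_per_mirna
        picked: list[str] = []
        while len(picked) < n_false:
            cand = rng.choice(config.n_genes, size=n_false - len(picked),
                              replace=False)
            picked += [genes[i] for i in cand
                       if genes[i] not in excluded]
            excluded.update(picked)
        rows_m += [m] * n_false
        rows_g += picked
        labels += [0] * n_false
    labels = np.asarray(labels)
    X = np.empty((len(labels), len(algs)))
    X[labels == 1] = _draw_scores(rng, int((labels == 1).sum()), config, True)
    X[labels == 0] = _draw_scores(rng, int((labels == 0).sum()), config, False)
    candidates = pd.DataFrame(X, columns=algs)
    candidates.insert(0, "gene_id", rows_g)
    candidates.insert(0, "mirna_id", rows_m)
    return ScoreSimulation(training, candidates, labels)


@dataclass
class GeneSets:
    """Generated gene-set collection, serializable as GMT."""

    sets: dict[str, list[str]]

    def to_gmt_text(self) -> str:
        lines = [
            "\t".join([name, "synthetic"] + members)
            for name, members in self.sets.items()
        ]
        return "\n".join(lines) + "\n"

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_gmt_text())


def simulate_gene_sets(
    config: SimulationConfig,
    truth: GroundTruth,
) -> GeneSets:
    """Generate planted and background gene sets; updates the ground truth.

    Each planted set takes the configured fraction of its members from
    the co-targeted hub pool (disjointly across sets) and the rest from
    genes with no true-target assignment, so its true-target coverage is
    controlled.  Background sets are drawn uniformly from the universe.
    """
    if not truth.hub_genes:
        raise ValueError("ground truth carries no hub genes; run simulate_profiles")
    rng = config.rng(_GENESET_STREAM)
    genes = config.gene_ids
    true_target_genes = {g for (_, g) in truth.true_pairs}
    background_pool = np.array(
        [g for g in genes if g not in true_target_genes]
    )
    sets: dict[str, list[str]] = {}
    hub_cursor = 0
    truth.planted_sets = []
    for si in range(config.n_planted_sets):
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        n_true = int(round(config.planted_coverage * size))
        if hub_cursor + n_true > len(truth.hub_genes):
            raise ValueError(
                "requested planted coverage unattainable: hub gene pool exhausted"
            )
        members = truth.hub_genes[hub_cursor: hub_cursor + n_true]
        hub_cursor += n_true
        fill = rng.choice(len(background_pool), size=size - n_true, replace=False)
        members = members + [background_pool[i] for i in fill]
        name = f"PLANTED_SET_{si + 1:02d}"
        sets[name] = members
        truth.planted_sets.append(name)
    for si in range(config.n_background_sets):
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        picked = rng.choice(config.n_genes, size=size, replace=False)
        sets[f"RANDOM_SET_{si + 1:03d}"] = [genes[i] for i in picked]
    return GeneSets(sets)
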
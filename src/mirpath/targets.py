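"""Bayesian integration of miRNA target-prediction scores.

Several sequence-based algorithms (TargetScan, miRanda, PicTar, mirTarget,
PITA, DIANA-microT) each emit a confidence score for a candidate
miRNA–mRNA pair, on incompatible scales and with incomplete coverage.
This module combines them into a single posterior probability that the
pair is a genuine target.

Model.  Let y ∈ {0, 1} indicate a real target and x_a the score of
algorithm a.  Class-conditional score distributions are modelled as gamma
densities fitted per algorithm per class on a labelled training set
(validated targets vs constructed negatives).  Scores are assumed
conditionally independent given y (naive Bayes), so

    p(y=1 | x) = π L1 / (π L1 + (1 − π) L0),
    L_c = Π_a  [ d_ac · Gamma(x_a; k_ac, θ_ac) ]   if a scored the pair
              [ 1 − d_ac ]                          otherwise

where π is the class prior and d_ac the class-conditional detection rate
(the probability that algorithm a emits any prediction for a class-c
pair) — an algorithm's silence is itself weak evidence.  Pairs with
posterior strictly above a cutoff (default 0.6), plus all experimentally
validated pairs, populate the gene × miRNA scoring matrix B with
b = posterior (predicted) or b = 1.0 (validated).

Gamma support requires positive scores; algorithms whose raw scale is
negative-oriented must be standardized first (see ``standardize_scores``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_ALGORITHMS",
    "GammaClassParams",
    "GammaLikelihoodModel",
    "standardize_scores",
    "fit_likelihoods",
    "posterior",
    "call_targets",
    "ScoringMatrix",
    "build_scoring_matrix",
]

DEFAULT_ALGORITHMS = (
    "targetscan", "miranda", "pictar", "mirtarget", "pita", "diana_microt",
)


@dataclass
class GammaClassParams:
    """Gamma(shape, scale) fit plus detection rate for one algorithm/class."""

    shape: float
    scale: float
    detection_rate: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("gamma shape and scale must be strictly positive")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ValueError("detection rate must lie in [0, 1]")


@dataclass
class GammaLikelihoodModel:
    """Per-algorithm class-conditional gamma likelihoods and class prior."""

    algorithms: tuple[str, ...]
    pos: dict[str, GammaClassParams]
    neg: dict[str, GammaClassParams]
    prior: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prior < 1.0:
            raise ValueError("prior must lie strictly between 0 and 1")
        for a in self.algorithms:
            if a not in self.pos or a not in self.neg:
                raise ValueError(f"missing fitted parameters for algorithm {a!r}")


def standardize_scores(
    scores: pd.DataFrame,
    orientations: dict[str, int] | None = None,
    shift_eps: float = 1e-6,
) -> pd.DataFrame:
    """Map raw algorithm scores onto positive support for gamma fitting.

    ``orientations[alg] = -1`` flips algorithms where more-negative means a
    stronger prediction (e.g. binding-energy scales).  After any flip, a
    column whose minimum is ≤ 0 is shifted so its minimum becomes
    ``shift_eps``.  NaN (no prediction) is preserved.
    """
    out = scores.copy()
    orientations = orientations or {}
    for col in out.columns:
        if orientations.get(col, 1) == -1:
            out[col] = -out[col]
        lo = out[col].min(skipna=True)
        if pd.notna(lo) and lo <= 0:
            out[col] = out[col] - lo + shift_eps
    return out


def fit_likelihoods(
    scores: pd.DataFrame,
    labels: np.ndarray,
    algorithms: tuple[str, ...] | None = None,
    min_observed: int = 30,
) -> GammaLikelihoodModel:
    """Fit per-algorithm gamma likelihoods on a labelled training set.

    Parameters
    ----------
    scores : DataFrame with one column per algorithm; NaN = no prediction.
    labels : array of {0, 1}, one per row (1 = validated target).
    min_observed : minimum observed scores per algorithm per class.

    The prior is the positive fraction of the training pairs and the
    detection rates are the observed fractions per class.  Gamma
    parameters are maximum-likelihood fits (location fixed at 0) started
    from the method-of-moments estimate.
    """
    algorithms = tuple(algorithms or scores.columns)
    labels = np.asarray(labels)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be 0 or 1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            "training set must contain both classes "
            f"(got {n_pos} positives, {n_neg} negatives)"
        )
    prior = n_pos / (n_pos + n_neg)

    fits: dict[int, dict[str, GammaClassParams]] = {0: {}, 1: {}}
    for a in algorithms:
        col = scores[a].to_numpy(dtype=float)
        for cls in (1, 0):
            x = col[labels == cls]
            obs = x[~np.isnan(x)]
            if len(obs) < min_observed:
                raise ValueError(
                    f"algorithm {a!r}, class {cls}: only {len(obs)} observed "
                    f"scores (need >= {min_observed})"
                )
            if (obs <= 0).any():
                raise ValueError(
                    f"algorithm {a!r}, class {cls}: non-positive scores; "
                    "standardize_scores() must be applied first"
                )
            mean, var = obs.mean(), obs.var()
            if var == 0.0:
                raise ValueError(
                    f"algorithm {a!r}, class {cls}: zero score variance, "
                    "gamma fit is degenerate"
                )
            shape0 = mean**2 / var  # method-of-moments start
            shape, _, scale = gamma_dist.fit(obs, shape0, floc=0)
            fits[cls][a] = GammaClassParams(
                shape=float(shape),
                scale=float(scale),
                detection_rate=len(obs) / len(x),
            )
    return GammaLikelihoodModel(algorithms, fits[1], fits[0], prior)


def _log_likelihoods(
    X: np.ndarray, obs: np.ndarray, model: GammaLikelihoodModel, cls: dict
) -> np.ndarray:
    ll = np.zeros(X.shape[0])
    for a_idx, a in enumerate(model.algorithms):
        p = cls[a]
        x = X[:, a_idx]
        o = obs[:, a_idx]
        dens = np.full(X.shape[0], np.log1p(-p.detection_rate) if p.detection_rate < 1
                       else -np.inf)
        if o.any():
            lp = gamma_dist.logpdf(x[o], p.shape, scale=p.scale)
            if np.isnan(lp).any():
                raise ValueError(f"algorithm {a!r}: invalid score produced NaN density")
            dens[o] = np.log(p.detection_rate) + lp
        ll += dens
    return ll


def posterior(
    scores: pd.DataFrame | pd.Series | dict,
    model: GammaLikelihoodModel,
) -> np.ndarray | float:
    """Posterior probability p(y=1 | observed scores) for candidate pairs.

    Accepts a DataFrame (one row per pair) or a single pair as a
    Series/dict; NaN marks an algorithm with no prediction.  Every pair
    must carry at least one observed score.  Returns the unclipped
    posterior in [0, 1] (an ndarray for frames, a float for single pairs).
    """
    single = not isinstance(scores, pd.DataFrame)
    if single:
        frame = pd.DataFrame([dict(scores)])
    else:
        frame = scores
    X = frame.reindex(columns=list(model.algorithms)).to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if (~obs).all(axis=1).any():
        raise ValueError("every pair needs at least one observed score")
    if (X[obs] <= 0).any():
        raise ValueError("scores must be positive; apply standardize_scores()")
    ll1 = _log_likelihoods(X, obs, model, model.pos)
    ll0 = _log_likelihoods(X, obs, model, model.neg)
    log_odds = np.log(model.prior) - np.log1p(-model.prior) + ll1 - ll0
    post = expit(log_odds)
    return float(post[0]) if single else post


def call_targets(
    pairs: pd.DataFrame,
    posteriors: np.ndarray,
    validated: pd.DataFrame | None = None,
    threshold: float = 0.6,
) -> pd.DataFrame:
    """Threshold posteriors into target calls and merge validated pairs.

    ``pairs`` needs columns mirna_id and gene_id aligned with
    ``posteriors``.  A predicted pair is called iff posterior > threshold
    (strict).  Validated pairs are called unconditionally: ones already in
    the candidate list are re-labelled source='validated'; novel ones are
    appended with posterior NaN.

    Returns a frame with columns mirna_id, gene_id, posterior, source
    ('predicted' | 'validated'), is_called.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    out = pairs[["mirna_id", "gene_id"]].copy()
    out["posterior"] = np.asarray(posteriors, dtype=float)
    out["source"] = "predicted"
    out["is_called"] = out["posterior"] > threshold
    if validated is not None and len(validated):
        key = pd.MultiIndex.from_frame(out[["mirna_id", "gene_id"]])
        vkey = pd.MultiIndex.from_frame(validated[["mirna_id", "gene_id"]])
        hit = key.isin(vkey)
        out.loc[hit, "source"] = "validated"
        out.loc[hit, "is_called"] = True
        novel = validated.loc[~vkey.isin(key), ["mirna_id", "gene_id"]].copy()
        if len(novel):
            novel["posterior"] = np.nan
            novel["source"] = "validated"
            novel["is_called"] = True
            out = pd.concat([out, novel], ignore_index=True)
    return out


@dataclass
class ScoringMatrix:
    """Gene × miRNA matrix B of target-prediction strengths in [0, 1]."""

    gene_ids: list[str]
    mirna_ids: list[str]
    b: np.ndarray
    n_dropped: int = 0  # pairs outside the declared universe

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (len(self.gene_ids), len(self.mirna_ids)):
            raise ValueError("b shape does not match the id lists")
        if ((self.b < 0) | (self.b > 1)).any():
            raise ValueError("prediction strengths must lie in [0, 1]")

    def to_triplets(self) -> pd.DataFrame:
        gi, mi = np.nonzero(self.b)
        return pd.DataFrame(
            {
                "gene_id": [self.gene_ids[i] for i in gi],
                "mirna_id": [self.mirna_ids[j] for j in mi],
                "b": self.b[gi, mi],
            }
        )

    @property
    def targeted_genes(self) -> np.ndarray:
        """Boolean mask over genes with nonzero strength for >= 1 miRNA."""
        return (self.b > 0).any(axis=1)


def build_scoring_matrix(
    calls: pd.DataFrame,
    gene_ids: list[str],
    mirna_ids: list[str],
) -> ScoringMatrix:
    """Assemble B from called pairs over a declared gene/miRNA universe.

    b = 1.0 for validated pairs, the posterior for called predicted pairs,
    0 otherwise.  Duplicate (gene, miRNA) entries resolve by max.  Pairs
    referencing ids outside the universe are dropped, counted and logged.
    """
    gpos = {g: i for i, g in enumerate(gene_ids)}
    mpos = {m: j for j, m in enumerate(mirna_ids)}
    b = np.zeros((len(gene_ids), len(mirna_ids)))
    n_dropped = 0
    called = calls[calls["is_called"]]
    for row in called.itertuples(index=False):
        gi = gpos.get(row.gene_id)
        mj = mpos.get(row.mirna_id)
        if gi is None or mj is None:
            n_dropped += 1
            continue
        value = 1.0 if row.source == "validated" else float(row.posterior)
        if value > b[gi, mj]:
            b[gi, mj] = value
    if n_dropped:
        logger.warning(
            "%d called pairs referenced ids outside the universe and were dropped",
            n_dropped,
        )
    return ScoringMatrix(list(gene_ids), list(mirna_ids), b, n_dropped)
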
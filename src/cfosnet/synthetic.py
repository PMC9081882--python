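"""Gaussian-copula synthetic cohorts with known Spearman ground truth.

The study design being emulated - two conditions of n = 8 animals, 30
lateralized regions, positive right-skewed densities, condition-dependent
correlation structure - has no public raw data, so every downstream stage
is exercised on simulated cohorts whose true correlation structure is
known exactly.

Sampling model
--------------
Given a target Spearman matrix ``rho_S``, the latent Gaussian correlation
is obtained from the exact bivariate-normal relation

    rho_P = 2 sin(pi * rho_S / 6),

repaired to the nearest positive semi-definite correlation matrix when
needed (eigenvalue clipping at 1e-8 plus diagonal renormalization; the
Frobenius repair distance is logged, and a distance above 0.1 is an error
naming the worst pairs).  Latent multivariate-normal draws are mapped
through per-region log-normal quantile functions parameterized by median
(cells/mm^2) and coefficient of variation.  Because ranks are invariant
under the strictly increasing marginal map, the sample Spearman structure
converges to ``rho_S`` regardless of the marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import Atlas, CohortTable, default_atlas
from .network import FunctionalNetwork

logger = logging.getLogger("cfosnet")

__all__ = [
    "SyntheticSpec",
    "ConditionPairSpec",
    "GroundTruth",
    "RecoveryScore",
    "generate_cohort",
    "generate_condition_pair",
    "recovery_score",
    "study_preset",
    "STUDY_PRESET",
]

#: maximum tolerated Frobenius distance of the PSD repair
REPAIR_TOLERANCE = 0.1

#: study-emulation preset (data, not code): design sizes, baseline
#: within-system coupling, planted condition-B effects, and per-system
#: log-normal marginals (median cells/mm^2, coefficient of variation).
STUDY_PRESET: dict = {
    "n_animals": 8,
    "condition_a": "no_stimulation",
    "condition_b": "stimulated",
    "base_within_system_rho": 0.15,
    "effect_global": 0.35,
    "effect_interhemi": 0.15,
    "effect_lc": 0.4,
    "marginals": {
        # medians span the order of magnitude seen in cortical vs nuclear
        # immediate-early-gene counts; CV 0.4 gives realistic animal scatter
        "cortical": {"median": 250.0, "cv": 0.4},
        "hippocampal": {"median": 150.0, "cv": 0.4},
        "amygdalar": {"median": 120.0, "cv": 0.4},
        "thalamic": {"median": 200.0, "cv": 0.4},
        "brainstem": {"median": 180.0, "cv": 0.4},
    },
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one simulated cohort.

    Attributes
    ----------
    n_animals : int
    atlas : Atlas
    target_spearman : ndarray
        Symmetric matrix of desired pairwise Spearman coefficients; unit
        diagonal, off-diagonal entries in (-1, 1).
    marginal_medians, marginal_cvs : ndarray
        Per-region log-normal median (> 0, cells/mm^2) and coefficient of
        variation (> 0).
    seed : int
    condition : str
    """

    n_animals: int
    atlas: Atlas
    target_spearman: np.ndarray = field(repr=False)
    marginal_medians: np.ndarray = field(repr=False)
    marginal_cvs: np.ndarray = field(repr=False)
    seed: int
    condition: str = "synthetic"

    def validate(self) -> None:
        d = len(self.atlas)
        T = self.target_spearman
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if T.shape != (d, d):
            raise ValueError(f"target_spearman shape {T.shape} != ({d}, {d})")
        if not np.allclose(T, T.T):
            raise ValueError("target_spearman must be symmetric")
        if not np.allclose(np.diag(T), 1.0):
            raise ValueError("target_spearman diagonal must be 1")
        off = T[~np.eye(d, dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("off-diagonal target Spearman entries must be in (-1, 1)")
        if self.marginal_medians.shape != (d,) or self.marginal_cvs.shape != (d,):
            raise ValueError("marginal parameter vectors must have one entry per region")
        if np.any(self.marginal_medians <= 0) or np.any(self.marginal_cvs <= 0):
            raise ValueError("marginal medians and CVs must be positive")


def _spearman_to_pearson(rho_s: np.ndarray) -> np.ndarray:
    rho_p = 2.0 * np.sin(np.pi * rho_s / 6.0)
    np.fill_diagonal(rho_p, 1.0)
    return rho_p


def _nearest_psd_correlation(R: np.ndarray, eig_floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Clip eigenvalues at ``eig_floor`` and renormalize the diagonal."""
    w, V = np.linalg.eigh(R)
    if w.min() >= eig_floor:
        return R, 0.0
    w_clipped = np.clip(w, eig_floor, None)
    repaired = (V * w_clipped) @ V.T
    scale = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(scale, scale)
    np.fill_diagonal(repaired, 1.0)
    return repaired, float(np.linalg.norm(repaired - R))


def generate_cohort(spec: SyntheticSpec) -> CohortTable:
    """Sample one cohort from its Gaussian-copula specification.

    Deterministic given ``spec.seed``.  Raises if the latent correlation
    target needs a PSD repair with Frobenius distance above
    ``REPAIR_TOLERANCE`` (the error names the most distorted pairs).
    """
    spec.validate()
    d = len(spec.atlas)
    latent = _spearman_to_pearson(spec.target_spearman)
    repaired, dist = _nearest_psd_correlation(latent)
    if dist > 0:
        logger.info("PSD repair applied: Frobenius distance %.4f", dist)
    if dist > REPAIR_TOLERANCE:
        delta = np.abs(repaired - latent)
        iu = np.triu_indices(d, k=1)
        order = np.argsort(delta[iu])[::-1][:5]
        codes = spec.atlas.codes
        worst = [
            f"{codes[iu[0][k]]}~{codes[iu[1][k]]} (|change|={delta[iu][k]:.3f})"
            for k in order
        ]
        raise ValueError(
            "infeasible target Spearman structure: PSD repair distance "
            f"{dist:.3f} > {REPAIR_TOLERANCE}; worst pairs: {', '.join(worst)}"
        )
    rng = np.random.default_rng(spec.seed)
    L = np.linalg.cholesky(repaired + 1e-12 * np.eye(d))
    Z = rng.standard_normal((spec.n_animals, d)) @ L.T
    # log-normal marginal: median m, CV c -> mu = ln m, sigma = sqrt(ln(1+c^2))
    mu = np.log(spec.marginal_medians)
    sigma = np.sqrt(np.log1p(spec.marginal_cvs**2))
    X = np.exp(mu + sigma * Z)
    data = pd.DataFrame(
        X,
        index=[f"{spec.condition}_{i+1:02d}" for i in range(spec.n_animals)],
        columns=spec.atlas.codes,
    )
    return CohortTable(condition=spec.condition, data=data, atlas=spec.atlas)


# ---------------------------------------------------------------------------
# Condition pairs with planted effects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionPairSpec:
    """Two-condition design: a base spec plus planted condition-B effects.

    ``effect_global`` raises every off-diagonal target uniformly;
    ``effect_interhemi`` raises homotopic (region vs its contralateral
    mirror) couplings; ``effect_lc`` raises the left-right locus coeruleus
    coupling and every LC-dentate gyrus pairing.  Condition A uses the base
    target unchanged; both conditions share marginals.
    """

    base: SyntheticSpec
    effect_global: float = 0.0
    effect_interhemi: float = 0.0
    effect_lc: float = 0.0
    condition_b: str = "stimulated"

    def target_b(self) -> np.ndarray:
        atlas = self.base.atlas
        codes = atlas.codes
        d = len(codes)
        T = self.base.target_spearman.copy()
        names = [c[: c.rfind("-")] for c in codes]
        hemis = [atlas[c].hemisphere for c in codes]
        for i in range(d):
            for j in range(i + 1, d):
                v = T[i, j] + self.effect_global
                if hemis[i] != hemis[j] and names[i] == names[j]:
                    v += self.effect_interhemi
                pair = {names[i], names[j]}
                if pair == {"LC"} or pair == {"LC", "DG"}:
                    v += self.effect_lc
                T[i, j] = T[j, i] = v
        return T


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure returned alongside a simulated condition pair."""

    target_a: np.ndarray
    target_b: np.ndarray
    edges_a: frozenset[frozenset[str]]
    edges_b: frozenset[frozenset[str]]


def _true_edges(atlas: Atlas, target: np.ndarray) -> frozenset[frozenset[str]]:
    codes = atlas.codes
    d = len(codes)
    return frozenset(
        frozenset((codes[i], codes[j]))
        for i in range(d)
        for j in range(i + 1, d)
        if target[i, j] != 0.0
    )


def generate_condition_pair(
    pair_spec: ConditionPairSpec,
) -> tuple[CohortTable, CohortTable, GroundTruth]:
    """Sample both condition cohorts and return the planted truth.

    The two cohorts share marginal parameters and differ only in target
    correlation structure; their seeds are derived independently from the
    base seed, so the pair is deterministic given the spec.
    """
    base = pair_spec.base
    seed_a, seed_b = np.random.SeedSequence(base.seed).generate_state(2) % (2**31)
    spec_a = replace(base, seed=int(seed_a))
    target_b = pair_spec.target_b()
    spec_b = replace(
        base, seed=int(seed_b), target_spearman=target_b, condition=pair_spec.condition_b
    )
    cohort_a = generate_cohort(spec_a)
    cohort_b = generate_cohort(spec_b)
    truth = GroundTruth(
        target_a=base.target_spearman.copy(),
        target_b=target_b,
        edges_a=_true_edges(base.atlas, base.target_spearman),
        edges_b=_true_edges(base.atlas, target_b),
    )
    return cohort_a, cohort_b, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryScore:
    sensitivity: float
    specificity: float
    false_edges: int
    true_positives: int
    false_negatives: int
    true_negatives: int


def recovery_score(
    inferred: FunctionalNetwork, truth: frozenset[frozenset[str]]
) -> RecoveryScore:
    """Confusion counts of an inferred edge set against the planted truth,
    over all unordered region-pair slots of the atlas."""
    all_pairs = {frozenset(p) for p in inferred.atlas.pair_codes()}
    found = inferred.edge_set()
    truth = frozenset(frozenset(p) for p in truth)
    tp = len(found & truth)
    fp = len(found - truth)
    fn = len(truth - found)
    tn = len(all_pairs) - tp - fp - fn
    sens = tp / len(truth) if truth else 1.0
    n_null = len(all_pairs) - len(truth)
    spec = tn / n_null if n_null else 1.0
    return RecoveryScore(
        sensitivity=sens,
        specificity=spec,
        false_edges=fp,
        true_positives=tp,
        false_negatives=fn,
        true_negatives=tn,
    )


# ---------------------------------------------------------------------------
# Study-emulation preset
# ---------------------------------------------------------------------------


def _preset_marginals(atlas: Atlas, preset: dict) -> tuple[np.ndarray, np.ndarray]:
    med = np.array([preset["marginals"][r.display_group]["median"] for r in atlas])
    cv = np.array([preset["marginals"][r.display_group]["cv"] for r in atlas])
    return med, cv


def _base_target(atlas: Atlas, within_rho: float) -> np.ndarray:
    d = len(atlas)
    T = np.eye(d)
    regions = list(atlas)
    for i in range(d):
        for j in range(i + 1, d):
            ri, rj = regions[i], regions[j]
            if ri.hemisphere == rj.hemisphere and ri.display_group == rj.display_group:
                T[i, j] = T[j, i] = within_rho
    return T


def study_preset(
    seed: int, n_animals: int | None = None, atlas: Atlas | None = None
) -> ConditionPairSpec:
    """The default study-emulation design as a :class:`ConditionPairSpec`.

    Two conditions of n = 8 animals on the 30-region atlas.  Condition A
    carries baseline within-system coupling only; condition B adds a
    uniform global rise, homotopic inter-hemispheric coupling, and the
    locus coeruleus effects (left-right LC plus LC-dentate gyrus), at the
    strengths recorded in :data:`STUDY_PRESET`.
    """
    preset = STUDY_PRESET
    atlas = atlas if atlas is not None else default_atlas()
    med, cv = _preset_marginals(atlas, preset)
    base = SyntheticSpec(
        n_animals=n_animals if n_animals is not None else preset["n_animals"],
        atlas=atlas,
        target_spearman=_base_target(atlas, preset["base_within_system_rho"]),
        marginal_medians=med,
        marginal_cvs=cv,
        seed=seed,
        condition=preset["condition_a"],
    )
    return ConditionPairSpec(
        base=base,
        effect_global=preset["effect_global"],
        effect_interhemi=preset["effect_interhemi"],
        effect_lc=preset["effect_lc"],
        condition_b=preset["condition_b"],
    )
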
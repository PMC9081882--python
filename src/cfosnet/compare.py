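"""Between-condition contrasts of c-Fos networks and densities.

Four comparison surfaces:

- total connectivity: the two conditions' all-pairs Fisher-z vectors
  compared by an unpaired two-sided Student t (df = n_a + n_b - 2) and by
  the Kruskal-Wallis test; both statistics are reported for every contrast
  because neither is privileged,
- node connectivity: the same two tests on one region's z-scores to every
  other region (29 values per condition on the default atlas) - used for
  the locus coeruleus contrast,
- hemispheric edge counts per anatomical area group (intra-left /
  intra-right / inter-hemisphere), counting significant edges of either
  sign with at least one endpoint in the group; an edge joining two groups
  contributes to both groups' counts,
- per-region density contrasts (t and Mann-Whitney), uncorrected p by
  default with Benjamini-Hochberg adjustment as an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import CohortTable
from .network import CorrelationResult, FunctionalNetwork, fisher_z

__all__ = [
    "TwoSampleTest",
    "ConditionContrast",
    "total_connectivity_contrast",
    "node_connectivity_contrast",
    "hemispheric_counts",
    "positive_fraction",
    "regional_density_contrast",
]

#: area groups summarized by the hemispheric edge-count table
COUNTED_GROUPS = ("frontal", "hippocampal", "amygdalar", "brainstem")


@dataclass
class TwoSampleTest:
    """Unpaired two-group comparison reported on both test surfaces.

    ``t`` is the equal-variance Student statistic with ``df = n_a+n_b-2``;
    ``kw_h`` is the Kruskal-Wallis H (rank-based, two groups).
    """

    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    df: int
    p_t: float
    kw_h: float
    p_kw: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _two_sample(a: np.ndarray, b: np.ndarray) -> TwoSampleTest:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    t_res = stats.ttest_ind(a, b, equal_var=True)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        kw_h, p_kw = 0.0, 1.0  # degenerate: all values identical
    else:
        kw_h, p_kw = stats.kruskal(a, b)
    t_stat = float(t_res.statistic)
    p_t = float(t_res.pvalue)
    if not np.isfinite(t_stat):  # identical constant groups
        t_stat, p_t = 0.0, 1.0
    return TwoSampleTest(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sem_a=float(stats.sem(a)),
        sem_b=float(stats.sem(b)),
        n_a=int(a.size),
        n_b=int(b.size),
        t=t_stat,
        df=int(a.size + b.size - 2),
        p_t=p_t,
        kw_h=float(kw_h),
        p_kw=float(p_kw),
    )


def total_connectivity_contrast(z_a: np.ndarray, z_b: np.ndarray) -> TwoSampleTest:
    """Compare the all-pairs connectivity strengths of two conditions.

    ``z_a`` and ``z_b`` are the unthresholded Fisher-z vectors (one value
    per region pair, 435 each for the default atlas, giving df = 868).
    """
    return _two_sample(z_a, z_b)


def node_connectivity_contrast(
    corr_a: CorrelationResult, corr_b: CorrelationResult, node: str
) -> TwoSampleTest:
    """Compare one region's connectivity strengths to all other regions.

    Extracts the node's Fisher-z scores against every other region from
    each condition's correlation matrix and applies the same two tests as
    :func:`total_connectivity_contrast`.
    """
    vecs = []
    for corr in (corr_a, corr_b):
        if node not in corr.atlas.codes:
            raise KeyError(f"unknown node {node!r}")
        idx = corr.atlas.index(node)
        row = np.delete(corr.rho[idx], idx)
        row = row[~np.isnan(row)]
        if row.size == 0:
            raise ValueError(f"node {node!r} has no defined correlations")
        vecs.append(np.asarray(fisher_z(row), dtype=float))
    return _two_sample(*vecs)


def hemispheric_counts(net: FunctionalNetwork) -> dict[str, dict[str, int]]:
    """Intra-/inter-hemisphere significant-edge counts per area group.

    For each of the four named area groups, counts the significant edges
    (either sign) having at least one endpoint in the group:
    ``intra_left`` / ``intra_right`` when both endpoints lie in the same
    hemisphere, ``inter`` otherwise.  An edge whose endpoints belong to two
    different groups is counted in both groups.
    """
    counts = {g: {"intra_left": 0, "intra_right": 0, "inter": 0} for g in COUNTED_GROUPS}
    atlas = net.atlas
    for e in net.edges:
        ri, rj = atlas[e.region_i], atlas[e.region_j]
        if ri.hemisphere != rj.hemisphere:
            slot = "inter"
        elif ri.hemisphere == "left":
            slot = "intra_left"
        else:
            slot = "intra_right"
        for group in {ri.area_group, rj.area_group}:
            if group in counts:
                counts[group][slot] += 1
    return counts


def positive_fraction(corr: CorrelationResult) -> float:
    """Share of defined region pairs with rho > 0."""
    iu = np.triu_indices(len(corr.atlas), k=1)
    rho = corr.rho[iu]
    rho = rho[~np.isnan(rho)]
    if rho.size == 0:
        raise ValueError("no defined correlation pairs")
    return float((rho > 0).mean())


def regional_density_contrast(
    cohort_a: CohortTable, cohort_b: CohortTable, fdr: bool = False
) -> pd.DataFrame:
    """Per-region two-group density comparison between conditions.

    For each atlas region, compares the two cohorts' densities with an
    unpaired t-test and a Mann-Whitney U test (uncorrected two-sided p).
    With ``fdr=True`` Benjamini-Hochberg adjusted columns are appended.
    Regions with fewer than two non-missing values in either cohort are
    flagged in the ``skipped`` column and carry NaN statistics.
    """
    if cohort_a.atlas.codes != cohort_b.atlas.codes:
        raise ValueError("cohorts must share the same atlas")
    rows = []
    for code in cohort_a.atlas.codes:
        a = cohort_a.data[code].dropna().to_numpy()
        b = cohort_b.data[code].dropna().to_numpy()
        if a.size < 2 or b.size < 2:
            rows.append(
                dict(region=code, mean_a=np.nan, mean_b=np.nan, t=np.nan,
                     p_t=np.nan, u=np.nan, p_u=np.nan, skipped=True)
            )
            continue
        t_res = stats.ttest_ind(a, b, equal_var=True)
        t_stat, p_t = float(t_res.statistic), float(t_res.pvalue)
        if not np.isfinite(t_stat):
            t_stat, p_t = 0.0, 1.0
        u_res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            dict(region=code, mean_a=float(a.mean()), mean_b=float(b.mean()),
                 t=t_stat, p_t=p_t, u=float(u_res.statistic),
                 p_u=float(u_res.pvalue), skipped=False)
        )
    table = pd.DataFrame(rows)
    if fdr:
        for col in ("p_t", "p_u"):
            mask = table[col].notna()
            adj = np.full(len(table), np.nan)
            adj[mask.to_numpy()] = stats.false_discovery_control(
                table.loc[mask, col].to_numpy(), method="bh"
            )
            table[col + "_bh"] = adj
    return table


@dataclass
class ConditionContrast:
    """Bundle of every between-condition comparison the pipeline reports."""

    label_a: str
    label_b: str
    total_connectivity: TwoSampleTest
    lc_contrast: dict[str, TwoSampleTest]
    hemispheric_counts: dict[str, dict[str, dict[str, int]]]
    positive_fraction: dict[str, float]
    density_tests: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "label_a": self.label_a,
            "label_b": self.label_b,
            "total_connectivity": self.total_connectivity.to_dict(),
            "lc_contrast": {k: v.to_dict() for k, v in self.lc_contrast.items()},
            "hemispheric_counts": self.hemispheric_counts,
            "positive_fraction": self.positive_fraction,
            "density_tests": self.density_tests.to_dict(orient="records"),
        }
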
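"""Mutation-spectrum summaries, accumulation-rate models and cohort tests.

Burdens are defined from the thresholded (sub-0.01) variant table: a
sample's per-bp burden in a region is the sum of its variant frequencies
over the region's positions divided by the region length, and the per-mtDNA
burden is the same sum (burden x region length), so the two are related by
the region length exactly.  Per-base-change means divide by the region
length as well, which makes the strand-bias statistic
Delta[G>A]-[C>T] = mean(G>A) - mean(C>T) antisymmetric by construction.

Age accumulation is modelled linearly: ordinary least squares of burden on
age with a t-based 95% CI on the slope.  Predictions are either from the
fitted line (``intercept + slope x age``) or anchored to an external
baseline load measured in infancy (``baseline + slope x age``), the form
used for SNV loads with the published forebrain baseline 0.37e-5 bp^-1.
Cohort comparisons are exact two-tailed Mann-Whitney rank tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import CircularGenome, RegionAnnotation
from .simulate import BASE_CHANGES

#: external forebrain baseline SNV load at <1 year (per bp)
FOREBRAIN_BASELINE_BP = 0.37e-5


# ---------------------------------------------------------------------------
# spectrum summaries


def region_positions(annot: RegionAnnotation, region: str) -> np.ndarray:
    if region == "all":
        return np.arange(1, annot.L + 1)
    if region == "control":
        return np.flatnonzero(annot._is_control)
    if region == "coding":
        return np.flatnonzero(~annot._is_control[1:]) + 1
    if region in annot.GENE_CLASSES:
        return np.flatnonzero(annot._gene_class == region)
    raise ValueError(f"unknown region {region!r}")


def summarize_spectrum(
    table: pd.DataFrame,
    annot: RegionAnnotation,
    regions: tuple[str, ...] = ("all", "coding", "control", "rRNA", "tRNA", "protein_coding"),
    transitions_only: bool = False,
) -> pd.DataFrame:
    """Per-region burdens and per-base-change mean frequencies for one sample.

    Returns one row per region with ``burden_bp`` (bp^-1), ``burden_mtdna``
    (= burden_bp x region length) and one column per base change (bp^-1).
    """
    t = table
    if transitions_only and "transition" in t.columns:
        t = t[t["transition"]]
    rows = []
    for region in regions:
        pos = region_positions(annot, region)
        length = len(pos)
        sel = t[np.isin(t["pos"], pos)] if len(t) else t
        total = float(sel["frequency"].sum()) if len(sel) else 0.0
        row = {
            "region": region,
            "length": length,
            "burden_bp": total / length if length else 0.0,
            "burden_mtdna": total,
        }
        for change in BASE_CHANGES:
            if len(sel) and "change" in sel.columns:
                s = float(sel.loc[sel["change"] == change, "frequency"].sum())
            else:
                s = 0.0
            row[change] = s / length if length else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class BiasResult:
    """Reference-strand transition biases for one region of one sample."""

    region: str
    delta_ga_ct: float  # mean(G>A) - mean(C>T), bp^-1
    delta_tc_ag: float  # mean(T>C) - mean(A>G), bp^-1
    track: pd.DataFrame | None = None


def strand_bias(
    table: pd.DataFrame,
    annot: RegionAnnotation,
    region: str = "coding",
    window: int | None = None,
    exclude_positions: tuple[int, ...] = (),
) -> BiasResult:
    """[G>A]-[C>T] and [T>C]-[A>G] bias magnitudes on the reference strand.

    With ``window`` set, also returns a rolling-mean per-position bias track
    over windows of that many bp.  ``exclude_positions`` drops the listed
    sites (e.g. m.64 / m.16148) before computing the statistic.
    """
    t = table
    if exclude_positions:
        t = t[~t["pos"].isin(exclude_positions)]
    pos = region_positions(annot, region)
    length = len(pos)
    sel = t[np.isin(t["pos"], pos)] if len(t) else t

    def mean_freq(change: str) -> float:
        if not len(sel):
            return 0.0
        return float(sel.loc[sel["change"] == change, "frequency"].sum()) / length

    result = BiasResult(
        region=region,
        delta_ga_ct=mean_freq("G>A") - mean_freq("C>T"),
        delta_tc_ag=mean_freq("T>C") - mean_freq("A>G"),
    )
    if window:
        per_pos = np.zeros(annot.L + 1)
        if len(sel):
            ga = sel[sel["change"] == "G>A"]
            ct = sel[sel["change"] == "C>T"]
            np.add.at(per_pos, ga["pos"].to_numpy(), ga["frequency"].to_numpy())
            np.subtract.at(per_pos, ct["pos"].to_numpy(), ct["frequency"].to_numpy())
        series = pd.Series(per_pos[pos], index=pos)
        result.track = pd.DataFrame(
            {
                "pos": pos,
                "bias": series.rolling(window, min_periods=1, center=True).mean().to_numpy(),
            }
        )
    return result


def hotspot_3243(table: pd.DataFrame) -> pd.DataFrame:
    """Per-position variant frequencies across the m.3242-3244 hotspot.

    Returns one row per position with the most abundant alternate allele,
    its frequency, and the A>B frequency (sum over all non-reference
    alleles), which by construction is >= the A>G frequency at m.3243.
    Positions with no effective coverage are reported as missing (NaN), not
    zero.
    """
    rows = []
    for pos in (3242, 3243, 3244):
        sel = table[table["pos"] == pos]
        if not len(sel):
            rows.append(
                {"pos": pos, "top_alt": None, "top_freq": np.nan, "a_to_b": np.nan}
            )
            continue
        top = sel.loc[sel["frequency"].idxmax()]
        rows.append(
            {
                "pos": pos,
                "top_alt": top["alt"],
                "top_freq": float(top["frequency"]),
                "a_to_b": float(sel["frequency"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pathogenicity bins


@dataclass
class PathogenicityBins:
    """Predicted-pathogenicity grouping of protein-coding transition sites.

    Bin 1: score > 0.667 or nonsense; bin 2: 0.100 <= score <= 0.666;
    bin 3: synonymous or score < 0.100.  ``counts`` are bin base counts,
    ``mean_freq`` the mean transition frequency per bin (sum of variant
    frequencies / bin base count).
    """

    counts: dict[str, int]
    mean_freq: dict[str, float]
    missing_sites: int


def pathogenicity_summary(
    table: pd.DataFrame,
    scores: pd.DataFrame,
    high_cut: float = 0.667,
    low_cut: float = 0.100,
) -> PathogenicityBins:
    """Bin protein-coding transition sites by predicted pathogenicity.

    ``scores`` has one row per protein-coding position with columns
    pos, score, nonsense (bool), synonymous (bool).  Sites absent from the
    score table are excluded and counted in ``missing_sites``.
    """
    s = scores.copy()
    bins = np.where(
        (s["score"] > high_cut) | s["nonsense"].astype(bool),
        "high",
        np.where(s["synonymous"].astype(bool) | (s["score"] < low_cut), "low", "mid"),
    )
    s["bin"] = bins
    t = table
    if "transition" in t.columns:
        t = t[t["transition"]]
    freq_at = t.groupby("pos")["frequency"].sum()
    counts = {}
    mean_freq = {}
    for b in ("high", "mid", "low"):
        pos = s.loc[s["bin"] == b, "pos"]
        counts[b] = int(len(pos))
        total = float(np.nansum(freq_at.reindex(pos).to_numpy(dtype=float)))
        mean_freq[b] = total / max(1, len(pos))
    missing = 0
    if len(t):
        coding_called = t["pos"].unique()
        missing = int((~np.isin(coding_called, s["pos"])).sum())
    return PathogenicityBins(counts=counts, mean_freq=mean_freq, missing_sites=missing)


def synthetic_score_table(
    genome: CircularGenome,
    annot: RegionAnnotation,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic stand-in pathogenicity score table.

    Covers every protein-coding transition site with a Beta-distributed
    score plus nonsense/synonymous flags drawn with codon-position-like
    probabilities.  It is a synthetic placeholder for an externally supplied
    per-base score table (which this package consumes, never computes).
    Bases where MT-ATP6 overlaps MT-ATP8 are listed once (for MT-ATP8).
    """
    rng = np.random.default_rng(seed)
    pos = annot.protein_coding_positions()
    n = len(pos)
    score = rng.beta(1.2, 1.8, n)
    synonymous = rng.random(n) < 0.30
    nonsense = (~synonymous) & (rng.random(n) < 0.04)
    return pd.DataFrame(
        {
            "pos": pos,
            "score": np.round(score, 3),
            "nonsense": nonsense,
            "synonymous": synonymous,
        }
    )


# ---------------------------------------------------------------------------
# linear accumulation models


@dataclass
class LinearRateModel:
    """Linear age-accumulation model: burden = intercept + slope x age.

    ``baseline`` (optional) anchors predictions to an externally measured
    load in infancy: prediction(age) = baseline + slope x age.
    """

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    rmse: float
    n: int
    baseline: float | None = None

    def predict(self, age: float) -> float:
        if self.baseline is not None:
            return self.baseline + self.slope * age
        return self.intercept + self.slope * age

    def ci_contains(self, slope: float) -> bool:
        return self.slope_ci[0] <= slope <= self.slope_ci[1]


def fit_rate_model(
    ages,
    burdens,
    baseline: float | None = None,
) -> LinearRateModel:
    """Ordinary least squares burden-vs-age fit with t-based 95% CI."""
    ages = np.asarray(ages, dtype=float)
    burdens = np.asarray(burdens, dtype=float)
    if len(ages) < 3:
        raise ValueError("need at least 3 samples")
    if len(np.unique(ages)) < 2:
        raise ValueError("ages are all equal; slope is unidentifiable")
    res = sps.linregress(ages, burdens)
    dof = len(ages) - 2
    tcrit = sps.t.ppf(0.975, dof)
    resid = burdens - (res.intercept + res.slope * ages)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return LinearRateModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_ci=(float(res.slope - tcrit * res.stderr), float(res.slope + tcrit * res.stderr)),
        rmse=rmse,
        n=len(ages),
        baseline=baseline,
    )


def rate_model_from_table(
    slope: float, value: float, at_age: float, anchored_baseline: float | None = None
) -> LinearRateModel:
    """Build a model from a published rate and a load at a reference age.

    With ``anchored_baseline`` given, the model predicts
    baseline + slope x age; otherwise the intercept is chosen so that the
    model reproduces ``value`` at ``at_age``.
    """
    return LinearRateModel(
        slope=slope,
        intercept=value - slope * at_age,
        slope_ci=(slope, slope),
        rmse=0.0,
        n=0,
        baseline=anchored_baseline,
    )


def fold_change(model: LinearRateModel, age1: float = 25.0, age2: float = 80.0) -> float:
    """Predicted fold increase between two ages (3 significant figures)."""
    p1 = model.predict(age1)
    if p1 <= 0:
        raise ValueError(f"non-positive prediction at age {age1}")
    ratio = model.predict(age2) / p1
    return float(f"{ratio:.3g}")


# ---------------------------------------------------------------------------
# exact Mann-Whitney


@dataclass
class CohortComparison:
    U: float
    p_value: float
    n1: int
    n2: int
    method: str


def mann_whitney_exact(group_a, group_b, max_enumeration: int = 300_000) -> CohortComparison:
    """Two-tailed Mann-Whitney rank test with exact small-sample enumeration.

    For small groups the two-tailed P is computed by enumerating every
    assignment of the pooled observations to the two groups (mid-ranks for
    ties) and counting assignments whose U deviates from its mean at least
    as much as observed.  Larger groups fall back to scipy's implementation.
    Identical groups give P = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if not len(a) or not len(b):
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # mid-ranks
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    mu = n1 * n2 / 2
    if np.all(pooled == pooled[0]):
        return CohortComparison(u_obs, 1.0, n1, n2, "degenerate")
    n_comb = math.comb(n1 + n2, n1)
    if n_comb <= max_enumeration:
        dev = abs(u_obs - mu) - 1e-9
        hits = 0
        rank_sum_base = n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - rank_sum_base
            if abs(u - mu) >= dev:
                hits += 1
        p = hits / n_comb
        method = "exact_enumeration"
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        method = "scipy"
    return CohortComparison(u_obs, min(p, 1.0), n1, n2, method)
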
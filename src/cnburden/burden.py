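"""Copy-number burden statistics and cohort-level alteration analyses.

The central statistic is the burden (percent genome altered, PGA): the
fraction of usable autosomal bins lying in called loss or gain segments.
Cohort analyses built on it: burden quartiles, the loss/gain decomposition
with an exact test against random direction assignment, region carrier
frequencies by metastatic state and by quartile, Kolmogorov-Smirnov
association of region carriage with burden, multi-region burden dispersion
and within-patient region prevalence, and the battery of clinical
association tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import SegmentProfile
from .genome import GenomeBins
from .regions import REGION_CATALOGUE, Region

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class BurdenRecord:
    """Burden of one core: percent of usable autosomal genome altered,
    decomposed into loss and gain over the same denominator."""

    sample_id: str
    burden: float
    loss_pct: float
    gain_pct: float
    n_segments: int
    mode: str = "by_bin"


def compute_burden(profile: SegmentProfile, bins: GenomeBins,
                   mode: str = "by_bin") -> BurdenRecord:
    """Burden from a called segment profile.

    ``by_bin`` (default): percent of usable autosomal bins inside non-neutral
    segments — with constant-width bins this is the percent of genome
    altered.  ``by_segment``: percent of segments that are non-neutral.
    """
    seg = profile.segments
    auto_chroms = set(bins.df.loc[bins.autosomal, "chrom"].astype(str))
    auto = seg["chrom"].astype(str).isin(auto_chroms).to_numpy()
    seg = seg.loc[auto]
    if mode == "by_bin":
        denom = int(seg["n_bins"].sum())
        if denom == 0:
            raise ValueError("zero usable autosomal bins")
        loss = 100.0 * seg.loc[seg["call"] == -1, "n_bins"].sum() / denom
        gain = 100.0 * seg.loc[seg["call"] == 1, "n_bins"].sum() / denom
    elif mode == "by_segment":
        denom = len(seg)
        if denom == 0:
            raise ValueError("zero autosomal segments")
        loss = 100.0 * (seg["call"] == -1).sum() / denom
        gain = 100.0 * (seg["call"] == 1).sum() / denom
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return BurdenRecord(sample_id=profile.sample_id, burden=loss + gain,
                        loss_pct=float(loss), gain_pct=float(gain),
                        n_segments=len(seg), mode=mode)


def assign_quartiles(burdens) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Quartile labels Q1..Q4 from index-core burdens.

    Boundaries are the 25th/50th/75th linear-interpolation percentiles;
    values exactly on a boundary fall in the lower quartile.
    """
    b = np.asarray(burdens, dtype=float)
    if len(b) < 4:
        raise ValueError("need at least 4 index burdens for quartiles")
    if len(np.unique(b)) < 4:
        warnings.warn("fewer than 4 distinct burden values; degenerate quartiles")
    q25, q50, q75 = np.percentile(b, [25, 50, 75])
    labels = np.select([b <= q25, b <= q50, b <= q75],
                       ["Q1", "Q2", "Q3"], default="Q4")
    return labels, (float(q25), float(q50), float(q75))


# ---------------------------------------------------------------------------
# loss vs gain under random direction assignment


def exact_2x2_p(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric null)."""
    (a, b), (c, d) = table
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def loss_gain_random_test(index_df: pd.DataFrame, method: str = "binomial") -> pd.DataFrame:
    """Per burden quartile, test pooled loss vs gain altered-bin counts
    against random (equal-probability) direction assignment.

    ``index_df`` needs columns ``quartile``, ``loss_bins``, ``gain_bins``
    (per index core).  ``method='binomial'`` (default) is the exact binomial
    test of loss probability 1/2, which is calibrated for this null;
    ``method='fisher'`` is the 2x2 observed-vs-expected hypergeometric
    framing (anti-conservative for this null; retained for comparability).
    The odds ratio reported is observed loss:gain against the 1:1 expectation.
    BH adjustment is applied across quartiles.
    """
    rows = []
    for q in QUARTILE_LABELS:
        sub = index_df.loc[index_df["quartile"] == q]
        if sub.empty:
            warnings.warn(f"empty quartile {q}; skipped")
            continue
        loss = int(sub["loss_bins"].sum())
        gain = int(sub["gain_bins"].sum())
        total = loss + gain
        if total == 0:
            warnings.warn(f"quartile {q} has no altered bins; skipped")
            continue
        if method == "binomial":
            p = stats.binomtest(loss, total, 0.5, alternative="two-sided").pvalue
        elif method == "fisher":
            exp_loss = total // 2
            p = exact_2x2_p([[loss, gain], [exp_loss, total - exp_loss]])
        else:
            raise ValueError(f"unknown method {method!r}")
        odds = loss / gain if gain > 0 else np.inf
        rows.append({"quartile": q, "loss": loss, "gain": gain,
                     "odds_ratio": odds, "p": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# region carriers


def region_carriers(segments: pd.DataFrame, bins: GenomeBins,
                    regions=REGION_CATALOGUE) -> pd.DataFrame:
    """Carrier matrix: rows = sample_id, columns = region label, boolean.

    A sample carries a region alteration iff >= 1 called segment of matching
    direction overlaps >= 1 bin of the region.  ``segments`` is a cohort
    segment table with a ``sample_id`` column.
    """
    out = {}
    sample_ids = segments["sample_id"].unique()
    alt = segments.loc[segments["call"] != 0]
    for region in regions:
        lo, hi = region.bin_span(bins)
        hits = alt.loc[(alt["call"] == region.direction)
                       & (alt["first_bin"] <= hi - 1) & (alt["last_bin"] >= lo),
                       "sample_id"].unique()
        col = pd.Series(False, index=sample_ids)
        col[hits] = True
        out[region.label] = col
    return pd.DataFrame(out, index=pd.Index(sample_ids, name="sample_id"))


def region_frequency_by_group(carriers: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Percent of patients per group whose index core carries each region.

    ``carriers`` is the index-core carrier matrix (rows = patients);
    ``groups`` maps the same rows to group labels (metastatic state or
    burden quartile).
    """
    groups = groups.reindex(carriers.index)
    if groups.isna().any():
        raise ValueError("group label missing for some carriers rows")
    freq = carriers.groupby(groups).mean() * 100.0
    freq.index.name = "group"
    return freq


def ks_distance(x, y) -> float:
    """Two-sample KS distance D = sup |ECDF_x - ECDF_y|.

    Invariant to any strictly monotone transform of the pooled values.
    """
    return float(stats.ks_2samp(np.asarray(x, float), np.asarray(y, float)).statistic)


def ks_region_association(burdens: pd.Series, carriers: pd.DataFrame,
                          min_freq: float = 0.20) -> pd.DataFrame:
    """Two-sample KS comparison of burden in carriers vs non-carriers.

    Only regions with carrier frequency > ``min_freq`` are tested (per
    direction, as each catalogue region has a single direction).  The exact
    KS distribution is used when both groups have <= 25 members, the
    asymptotic one otherwise; BH across all tested regions.
    """
    burdens = burdens.reindex(carriers.index)
    rows = []
    for label in carriers.columns:
        mask = carriers[label].to_numpy()
        freq = mask.mean()
        if freq <= min_freq:
            continue
        x, y = burdens[mask].to_numpy(), burdens[~mask].to_numpy()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"region {label}: group with < 2 members; skipped")
            continue
        method = "exact" if max(len(x), len(y)) <= 25 else "asymp"
        res = stats.ks_2samp(x, y, method=method)
        rows.append({"region": label, "n_carriers": int(mask.sum()),
                     "carrier_freq": float(freq), "D": float(res.statistic),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# multi-region heterogeneity


def multiregion_dispersion(core_df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Within-patient burden SD across cores, compared between M0 and M1.

    ``core_df`` needs columns patient_id, burden, is_index, state.  Patients
    with a single core are excluded (count reported).  Returns the
    per-patient dispersion table and a summary dict with the Kruskal-Wallis
    M0-vs-M1 comparison and Spearman correlations of the SD with index
    burden and with core count.
    """
    rows = []
    n_singleton = 0
    for pid, sub in core_df.groupby("patient_id"):
        if len(sub) < 2:
            n_singleton += 1
            continue
        state = sub["state"].iloc[0]
        idx = sub.loc[sub["is_index"], "burden"]
        rows.append({"patient_id": pid, "n_cores": len(sub),
                     "burden_sd": float(sub["burden"].std(ddof=1)),
                     "index_burden": float(idx.iloc[0]) if len(idx) else np.nan,
                     "group": "M1" if str(state).startswith("M1") else "M0"})
    disp = pd.DataFrame(rows)
    summary = {"n_excluded_singleton": n_singleton, "n_patients": len(disp)}
    if not disp.empty and disp["group"].nunique() == 2:
        g0 = disp.loc[disp["group"] == "M0", "burden_sd"]
        g1 = disp.loc[disp["group"] == "M1", "burden_sd"]
        try:
            stat, p = stats.kruskal(g0, g1)
            summary["kruskal_p"] = float(p)
            summary["kruskal_stat"] = float(stat)
        except ValueError:   # all values identical (e.g. truncal_fraction 1)
            summary["kruskal_p"] = np.nan
        summary["median_sd_M0"] = float(g0.median())
        summary["median_sd_M1"] = float(g1.median())
    if len(disp) >= 3:
        rho_b, p_b = stats.spearmanr(disp["burden_sd"], disp["index_burden"])
        rho_n, p_n = stats.spearmanr(disp["burden_sd"], disp["n_cores"])
        summary.update(spearman_sd_vs_index_burden=float(rho_b), spearman_sd_vs_index_burden_p=float(p_b),
                       spearman_sd_vs_n_cores=float(rho_n), spearman_sd_vs_n_cores_p=float(p_n))
    return disp, summary


def region_prevalence_within_patient(core_carriers: pd.DataFrame,
                                     patient_ids: pd.Series,
                                     regions=REGION_CATALOGUE) -> pd.DataFrame:
    """Percent of a patient's cores carrying each region alteration.

    Patients enter a region's summary only with >= 2 cores and >= 1 carrier
    core.  Returns per-region rows with the per-patient median and IQR of
    the prevalence plus the number of eligible patients.
    """
    patient_ids = patient_ids.reindex(core_carriers.index)
    rows = []
    for region in regions:
        label = region.label if isinstance(region, Region) else str(region)
        if label not in core_carriers.columns:
            continue
        prevs = []
        for _, sub in core_carriers[label].groupby(patient_ids):
            if len(sub) >= 2 and sub.any():
                prevs.append(100.0 * sub.mean())
        if not prevs:
            continue
        prevs = np.array(prevs)
        rows.append({"region": label, "n_patients": len(prevs),
                     "median_prevalence": float(np.median(prevs)),
                     "iqr_low": float(np.percentile(prevs, 25)),
                     "iqr_high": float(np.percentile(prevs, 75))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# clinical association battery


def cohort_association_tests(index_df: pd.DataFrame) -> dict:
    """Burden-vs-clinical association battery on index cores.

    ``index_df`` needs columns burden, loss_pct, gain_pct, state,
    grading_group, psa, age, cellularity.  Reports rank-based group
    comparisons with medians and univariable linear regressions with
    sqrt(burden) as the response.  Missing covariates are dropped listwise
    per test, with counts recorded.
    """
    import statsmodels.api as sm

    df = index_df.copy()
    df["is_m1"] = df["state"].astype(str).str.startswith("M1")
    out = {}

    def _ranksum(name, a, b, la, lb):
        a, b = np.asarray(a, float), np.asarray(b, float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) == 0 or len(b) == 0:
            out[name] = {"p": np.nan}
            return
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        out[name] = {"p": float(p), f"median_{la}": float(np.median(a)),
                     f"median_{lb}": float(np.median(b)), "n": len(a) + len(b)}

    _ranksum("burden_M0_vs_M1", df.loc[~df.is_m1, "burden"], df.loc[df.is_m1, "burden"],
             "M0", "M1")
    _ranksum("burden_M0N0_vs_M0N1", df.loc[df.state == "M0N0", "burden"],
             df.loc[df.state == "M0N1", "burden"], "M0N0", "M0N1")
    _ranksum("burden_M1low_vs_M1high", df.loc[df.state == "M1low", "burden"],
             df.loc[df.state == "M1high", "burden"], "M1low", "M1high")

    def _kruskal(name, values, groups):
        sub = pd.DataFrame({"v": values, "g": groups}).dropna()
        samples = [s["v"].to_numpy() for _, s in sub.groupby("g") if len(s) > 0]
        if len(samples) < 2:
            out[name] = {"p": np.nan}
            return
        try:
            stat, p = stats.kruskal(*samples)
        except ValueError:
            stat, p = np.nan, np.nan
        out[name] = {"p": float(p), "n": int(len(sub)),
                     "medians": {str(g): float(s["v"].median()) for g, s in sub.groupby("g")}}

    _kruskal("burden_by_grading_group", df["burden"], df["grading_group"])
    _kruskal("cellularity_by_m_status", df["cellularity"], df["is_m1"].map({False: "M0", True: "M1"}))
    log_ratio = np.log((df["gain_pct"] + 0.1) / (df["loss_pct"] + 0.1))
    _kruskal("log_gain_loss_ratio_by_m_status", log_ratio,
             df["is_m1"].map({False: "M0", True: "M1"}))

    regressions = {}
    covs = {"is_m1": df["is_m1"].astype(float), "grading_group": df["grading_group"],
            "log_psa": np.log(df["psa"]), "age": df["age"], "cellularity": df["cellularity"]}
    for name, x in covs.items():
        sub = pd.DataFrame({"y": np.sqrt(df["burden"]), "x": x}).dropna()
        n_dropped = len(df) - len(sub)
        model = sm.OLS(sub["y"], sm.add_constant(sub["x"])).fit()
        regressions[name] = {"slope": float(model.params.iloc[1]),
                             "p": float(model.pvalues.iloc[1]),
                             "n": int(len(sub)), "n_dropped": n_dropped}
    out["sqrt_burden_regressions"] = regressions
    return out
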
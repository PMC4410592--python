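"""Per-probe single-case testing and hypomethylated DMR calling.

The region caller looks for imprinted-like differentially methylated
regions: runs of CpGs that are hemimethylated in controls (mean control
M between -1 and +1, i.e. beta near 0.5 as expected under parent-of-origin
monoallelic methylation), individually significant in the single-case test,
hypomethylated in the case (beta difference below zero), and consecutive
in genomic order with adjacent members no more than 2000 nt apart. Runs of
at least three such CpGs become region calls, annotated with Fisher's
combined probability (X² = -2 Σ ln pᵢ against chi-square with 2k df,
evaluated in log space so that astronomically small combined P values are
reported exactly rather than underflowing; the displayed P collapses to 0
below 10^-350).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import MethylationDataset, MValueMatrix, m_to_beta
from .singlecase import Method, batch_single_case

__all__ = [
    "FilterConfig",
    "RegionCall",
    "PROBE_RESULT_COLUMNS",
    "test_probes",
    "filter_candidates",
    "call_regions",
    "fisher_combine",
    "fdr_adjust",
    "control_titration",
]

#: column contract for per-probe result tables (index: probe_id)
PROBE_RESULT_COLUMNS = (
    "chrom", "pos", "t", "df", "p_one_tailed", "delta_m", "delta_beta",
    "control_mean_m", "effective_n",
)

#: smallest positive p accepted by Fisher combination (zero p is clamped here)
_MIN_P = np.nextafter(0.0, 1.0)

#: displayed combined P collapses to 0 below this magnitude
UNDERFLOW_LOG10 = -350.0


@dataclass(frozen=True)
class FilterConfig:
    """Candidate-probe and region-assembly thresholds.

    Defaults follow the single-sample criteria: one-tailed P < 0.05 with
    no multiplicity adjustment, control hemimethylation band M in [-1, +1],
    hypomethylation only, and at least three consecutive CpGs within
    2000 nt. ``stringent_fdr_threshold`` switches on the earlier cohort
    pipeline's rule (BH-FDR adjusted one-tailed P < 1e-7) when
    ``stringent`` is set.
    """

    p_threshold: float = 0.05
    stringent: bool = False
    stringent_fdr_threshold: float = 1e-7
    control_m_low: float = -1.0
    control_m_high: float = 1.0
    min_probes: int = 3
    max_gap_nt: int = 2000
    require_hypomethylation: bool = True
    call_hypermethylation: bool = False
    # "hemimethylated": an intervening retained hemimethylated non-candidate
    # probe breaks a run; "all_retained": any retained probe does.
    consecutive_scope: str = "hemimethylated"
    # "adjacent": the gap bound applies between adjacent members;
    # "span": it bounds the whole region span.
    gap_semantics: str = "adjacent"

    def __post_init__(self) -> None:
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if self.max_gap_nt <= 0:
            raise ValueError("max_gap_nt must be positive")
        if self.consecutive_scope not in ("hemimethylated", "all_retained"):
            raise ValueError(f"unknown consecutive_scope {self.consecutive_scope!r}")
        if self.gap_semantics not in ("adjacent", "span"):
            raise ValueError(f"unknown gap_semantics {self.gap_semantics!r}")


@dataclass(frozen=True)
class RegionCall:
    """A called region: 1-based inclusive span of its member probes."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]
    fisher_chi2: float
    fisher_df: int
    log10_p: float
    p_display: float
    mean_delta_m: float = math.nan

    @property
    def k(self) -> int:
        return len(self.probe_ids)


def test_probes(
    ds: MethylationDataset,
    m: MValueMatrix,
    method: Method | str = Method.CH,
) -> pd.DataFrame:
    """Apply a single-case test at every retained probe.

    Returns a DataFrame indexed by probe id with PROBE_RESULT_COLUMNS.
    ``p_one_tailed`` is the lower-tail probability (the hypomethylation
    direction for CH/WB; for OS the statistic's sign is flipped before
    taking the tail so that the column means the same thing for all
    methods). Beta differences are computed by mapping the normalized M
    values back to the beta scale. Untestable probes carry NaN statistics.
    """
    method = Method(method)
    case = ds.case_id
    controls = ds.control_ids
    if len(controls) < 2:
        raise ValueError(f"need >= 2 controls, have {len(controls)}")
    df = m.values
    case_m = df[case].to_numpy(dtype=float)
    ctrl_m = df[controls].to_numpy(dtype=float)
    results = batch_single_case(case_m, ctrl_m, method)
    # one-tailed hypomethylation p: lower tail for CH/WB, upper for OS
    if method is Method.OS:
        p_one = [r.p_upper for r in results]
    else:
        p_one = [r.p_lower for r in results]
    ctrl_mean_m = np.nanmean(ctrl_m, axis=1)
    case_beta = m_to_beta(case_m)
    ctrl_beta_mean = np.nanmean(m_to_beta(ctrl_m), axis=1)
    manifest = ds.manifest.loc[df.index]
    out = pd.DataFrame(
        {
            "chrom": manifest["chrom"].to_numpy(),
            "pos": manifest["pos"].to_numpy(),
            "t": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p_one_tailed": p_one,
            "delta_m": case_m - ctrl_mean_m,
            "delta_beta": case_beta - ctrl_beta_mean,
            "control_mean_m": ctrl_mean_m,
            "effective_n": [r.n for r in results],
        },
        index=df.index,
    )
    return out


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_candidates(results: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Select probes that are hemimethylated in controls, significant, and hypomethylated.

    In stringent mode the one-tailed p-values are BH-FDR adjusted first
    and compared to ``stringent_fdr_threshold``.
    """
    ok = results["t"].notna()
    hemi = results["control_mean_m"].between(cfg.control_m_low, cfg.control_m_high)
    if cfg.stringent:
        padj = pd.Series(np.ones(len(results)), index=results.index)
        padj[ok] = fdr_adjust(results.loc[ok, "p_one_tailed"])
        signif = padj < cfg.stringent_fdr_threshold
    else:
        signif = results["p_one_tailed"] < cfg.p_threshold
    mask = ok & hemi & signif
    if cfg.require_hypomethylation and not cfg.call_hypermethylation:
        mask &= results["delta_beta"] < 0
    elif cfg.call_hypermethylation:
        mask &= results["delta_beta"] > 0
    return results[mask]


def _chi2_log10_sf_even(x: float, df: int) -> float:
    """log10 of the chi-square survival function for even df, underflow-free.

    With df = 2k the survival function is the Erlang tail
    ``exp(-x/2) * sum_{j<k} (x/2)^j / j!``, evaluated here entirely in log
    space; scipy's logsf returns -inf once the plain sf underflows.
    """
    from scipy.special import gammaln, logsumexp

    k = df // 2
    half = x / 2.0
    if half <= 0:
        return 0.0
    j = np.arange(k)
    log_terms = j * math.log(half) - gammaln(j + 1)
    return float((-half + logsumexp(log_terms)) / math.log(10))


def fisher_combine(p_values) -> tuple[float, int, float, float]:
    """Fisher's combined probability over independent per-CpG tests.

    Returns (chi2, df, log10_p, p_display) with chi2 = -2 Σ ln pᵢ tested
    against chi-square with 2k df. The tail is evaluated in log space so
    the combined P never underflows; p_display is 10**log10_p, reported
    as 0 when log10_p < -350.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no probes: Fisher combination needs k >= 1 p-values")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("zero p-value clamped to smallest positive float")
        p = np.maximum(p, _MIN_P)
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    log10_p = _chi2_log10_sf_even(chi2, df)
    p_display = 0.0 if log10_p < UNDERFLOW_LOG10 else float(10.0 ** log10_p)
    return chi2, df, log10_p, p_display


def _sort_genomic(df: pd.DataFrame) -> pd.DataFrame:
    # position ties broken by probe id for determinism
    tmp = df.assign(_pid=df.index)
    tmp = tmp.sort_values(["chrom", "pos", "_pid"], kind="stable")
    return tmp.drop(columns="_pid")


def call_regions(
    candidates: pd.DataFrame,
    all_retained: pd.DataFrame,
    cfg: FilterConfig,
) -> list[RegionCall]:
    """Assemble candidate probes into maximal consecutive runs of >= min_probes.

    A run is consecutive in genomic order among the *scope* probes of its
    chromosome (default scope: retained hemimethylated probes, so an
    intervening hemimethylated probe that failed the candidate filter
    breaks the run), with every adjacent candidate pair at most
    ``max_gap_nt`` apart. Each qualifying run becomes a RegionCall whose
    Fisher statistic combines the member probes' one-tailed p-values.
    """
    if candidates.empty:
        return []
    if cfg.consecutive_scope == "hemimethylated":
        scope = all_retained[
            all_retained["control_mean_m"].between(cfg.control_m_low, cfg.control_m_high)
        ]
    else:
        scope = all_retained
    cand_ids = set(candidates.index)
    regions: list[RegionCall] = []
    for chrom, sub in _sort_genomic(scope).groupby("chrom", sort=True):
        run: list[str] = []

        def flush(run: list[str]) -> None:
            if len(run) >= cfg.min_probes:
                member = candidates.loc[run]
                chi2, fdf, log10_p, p_disp = fisher_combine(
                    member["p_one_tailed"].to_numpy()
                )
                regions.append(
                    RegionCall(
                        chrom=str(chrom),
                        start=int(member["pos"].min()),
                        end=int(member["pos"].max()),
                        probe_ids=tuple(run),
                        fisher_chi2=chi2,
                        fisher_df=fdf,
                        log10_p=log10_p,
                        p_display=p_disp,
                        mean_delta_m=float(member["delta_m"].mean()),
                    )
                )

        prev_pos: int | None = None
        for pid, row in sub.iterrows():
            if pid not in cand_ids:
                flush(run)
                run = []
                prev_pos = None
                continue
            pos = int(row["pos"])
            if run and prev_pos is not None:
                if cfg.gap_semantics == "adjacent":
                    gap_ok = pos - prev_pos <= cfg.max_gap_nt
                else:
                    gap_ok = pos - int(candidates.loc[run[0], "pos"]) <= cfg.max_gap_nt
                if not gap_ok:
                    flush(run)
                    run = []
            run.append(pid)
            prev_pos = pos
        flush(run)
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def control_titration(
    ds: MethylationDataset,
    m: MValueMatrix,
    sizes: tuple[int, ...] = (5, 10, 20, 30, 40, 50),
    replicates: int = 5,
    seed: int = 0,
    cfg: FilterConfig | None = None,
    method: Method | str = Method.CH,
    truth_regions: list[tuple[str, int, int]] | None = None,
) -> pd.DataFrame:
    """Assess how control-group size affects detection.

    For each requested size and replicate, controls are subsampled without
    replacement (seeded), the test -> filter -> region pipeline is rerun,
    and per run the number of candidate probes and called regions is
    reported, plus — when a truth set of (chrom, start, end) spans is
    supplied — the fraction of truth regions overlapped by a call and the
    mean effect size and noncentral-t interval width over probes inside
    the truth spans. Sizes larger than the control pool are skipped with
    a warning.
    """
    from .singlecase import ControlSummary, effect_size_interval
    cfg = cfg or FilterConfig()
    rng = np.random.default_rng(seed)
    pool = ds.control_ids
    records = []
    for size in sizes:
        if size > len(pool):
            import warnings

            warnings.warn(f"size {size} exceeds control pool ({len(pool)}); skipped")
            continue
        for rep in range(replicates):
            chosen = list(rng.choice(pool, size=size, replace=False))
            sub = ds.subset_samples([ds.case_id] + chosen)
            sub_m = MValueMatrix(m.values[[ds.case_id] + chosen], list(m.provenance))
            results = test_probes(sub, sub_m, method)
            cand = filter_candidates(results, cfg)
            regions = call_regions(cand, results, cfg)
            rec = {
                "size": size,
                "replicate": rep,
                "n_candidates": len(cand),
                "n_regions": len(regions),
            }
            if truth_regions:
                hit = sum(
                    any(
                        r.chrom == c and r.start <= e and r.end >= s
                        for r in regions
                    )
                    for c, s, e in truth_regions
                )
                rec["truth_detected"] = hit
                rec["truth_total"] = len(truth_regions)
                rec["sensitivity"] = hit / len(truth_regions)
                in_truth = pd.Series(False, index=results.index)
                for c, s, e in truth_regions:
                    in_truth |= (results["chrom"] == c) & results["pos"].between(s, e)
                zs, widths = [], []
                for pid in results.index[in_truth]:
                    row_ctrl = sub_m.values.loc[pid, chosen].to_numpy(dtype=float)
                    row_ctrl = row_ctrl[~np.isnan(row_ctrl)]
                    if row_ctrl.size < 2 or row_ctrl.std(ddof=1) == 0:
                        continue
                    es = effect_size_interval(
                        float(sub_m.values.loc[pid, ds.case_id]),
                        ControlSummary.from_scores(row_ctrl),
                    )
                    zs.append(es.z_cc)
                    widths.append(es.ci_upper - es.ci_lower)
                rec["truth_mean_z_cc"] = float(np.mean(zs)) if zs else math.nan
                rec["truth_mean_ci_width"] = (
                    float(np.mean(widths)) if widths else math.nan
                )
            records.append(rec)
    return pd.DataFrame.from_records(records)
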
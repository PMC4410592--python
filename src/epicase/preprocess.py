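"""Quality filtering and normalization of 450k-style methylation data.

The pipeline order is: drop probes with missing beta values, drop samples
failing detection-p QC, drop probes failing detection-p QC, remove sex
chromosomes, logit-transform beta to M values, quantile-normalize across
samples, and peak-correct Infinium type-II probes onto the type-I scale.
Batch correction is deliberately absent: the design requires each case and
its controls to come from the same array batch.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

log = logging.getLogger(__name__)

__all__ = [
    "MethylationDataset",
    "MValueMatrix",
    "EmptyDatasetError",
    "CaseFailedQCError",
    "normalize_chrom",
    "drop_missing_probes",
    "drop_failed_samples",
    "drop_failed_probes",
    "drop_sex_chromosomes",
    "beta_to_m",
    "m_to_beta",
    "quantile_normalize",
    "peak_correct",
    "preprocess_pipeline",
]

#: clamp for the logit transform, keeping M finite at beta = 0 or 1
LOGIT_EPS = 1e-6

MANIFEST_COLUMNS = ("chrom", "pos", "design_type")


class EmptyDatasetError(ValueError):
    """A filter removed every probe (or sample)."""


class CaseFailedQCError(ValueError):
    """The case sample failed quality control; the analysis is undefined."""


def normalize_chrom(name: str) -> str:
    """Normalize chromosome-name dialects ("X", "23", "chrX") to "chrN"."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        s = "X"
    elif s == "24":
        s = "Y"
    return "chr" + s.upper() if s.upper() in ("X", "Y", "M", "MT") else "chr" + s


@dataclass
class MethylationDataset:
    """Manifest + beta matrix + detection-p matrix + sample roles.

    ``manifest`` is indexed by probe id with columns (chrom, pos,
    design_type); ``beta`` and ``detection_p`` are probes-by-samples
    DataFrames sharing the manifest's index and a common column set.
    ``roles`` maps each sample id to "case" or "control".
    """

    manifest: pd.DataFrame
    beta: pd.DataFrame
    detection_p: pd.DataFrame
    roles: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.manifest.index.is_unique:
            dupes = self.manifest.index[self.manifest.index.duplicated()][:5]
            raise ValueError(f"duplicate probe ids in manifest: {list(dupes)}")
        for col in MANIFEST_COLUMNS:
            if col not in self.manifest.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if not self.beta.index.equals(self.manifest.index):
            raise ValueError("beta matrix rows do not match the manifest probes")
        if not self.detection_p.index.equals(self.beta.index):
            raise ValueError("detection-p rows do not match the beta matrix")
        if list(self.detection_p.columns) != list(self.beta.columns):
            raise ValueError(
                "detection-p columns do not match beta columns: "
                f"{sorted(set(self.beta.columns) ^ set(self.detection_p.columns))}"
            )
        missing = set(self.roles) - set(self.beta.columns)
        if missing:
            raise ValueError(f"role samples absent from matrices: {sorted(missing)}")
        vals = self.beta.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 1))
        if not ok.all():
            raise ValueError("beta values outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def case_id(self) -> str:
        cases = [s for s, r in self.roles.items() if r == "case"]
        if len(cases) != 1:
            raise ValueError(f"expected exactly one case sample, found {cases}")
        return cases[0]

    @property
    def control_ids(self) -> list[str]:
        return [s for s in self.beta.columns if self.roles.get(s) == "control"]

    def subset_probes(self, keep: pd.Index) -> "MethylationDataset":
        return MethylationDataset(
            self.manifest.loc[keep],
            self.beta.loc[keep],
            self.detection_p.loc[keep],
            dict(self.roles),
        )

    def subset_samples(self, keep: list[str]) -> "MethylationDataset":
        roles = {s: r for s, r in self.roles.items() if s in keep}
        return MethylationDataset(
            self.manifest, self.beta[keep], self.detection_p[keep], roles
        )


@dataclass
class MValueMatrix:
    """Probes-by-samples M values with a record of transformations applied."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def with_step(self, values: pd.DataFrame, step: str) -> "MValueMatrix":
        return MValueMatrix(values, self.provenance + [step])


def drop_missing_probes(ds: MethylationDataset) -> MethylationDataset:
    """Remove every CpG site with a missing beta value in any sample."""
    keep = ds.beta.index[ds.beta.notna().all(axis=1)]
    removed = len(ds.beta) - len(keep)
    log.info("drop_missing_probes: removed %d of %d probes", removed, len(ds.beta))
    if len(keep) == 0:
        raise EmptyDatasetError("all probes had missing values")
    return ds.subset_probes(keep)


def drop_failed_samples(
    ds: MethylationDataset, p_thresh: float = 0.05, frac: float = 0.90
) -> MethylationDataset:
    """Remove samples where more than ``frac`` of probes have detection p > ``p_thresh``.

    The inequalities are strict on both thresholds. Removing the case
    sample aborts: the single-sample analysis is undefined without it.
    """
    if not (0 < p_thresh < 1 and 0 < frac < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    fail_frac = (ds.detection_p > p_thresh).mean(axis=0)
    bad = [s for s in ds.sample_ids if fail_frac[s] > frac]
    if ds.case_id in bad:
        raise CaseFailedQCError(
            f"case sample {ds.case_id!r} failed detection-p QC "
            f"({100 * fail_frac[ds.case_id]:.1f}% probes > {p_thresh})"
        )
    log.info("drop_failed_samples: removed %d of %d samples %s",
             len(bad), len(ds.sample_ids), bad)
    keep = [s for s in ds.sample_ids if s not in bad]
    return ds.subset_samples(keep)


def drop_failed_probes(
    ds: MethylationDataset, p_thresh: float = 1e-5, frac: float = 0.75
) -> MethylationDataset:
    """Remove probes where more than ``frac`` of samples have detection p > ``p_thresh``."""
    if not (0 < p_thresh < 1 and 0 < frac < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    fail_frac = (ds.detection_p > p_thresh).mean(axis=1)
    keep = ds.beta.index[~(fail_frac > frac)]
    removed = len(ds.beta) - len(keep)
    log.info("drop_failed_probes: removed %d of %d probes", removed, len(ds.beta))
    if len(keep) == 0:
        raise EmptyDatasetError("all probes failed detection-p QC")
    return ds.subset_probes(keep)


def drop_sex_chromosomes(ds: MethylationDataset) -> MethylationDataset:
    """Remove X and Y probes to discard sex bias; accepts chrX/X/23 dialects."""
    chroms = ds.manifest["chrom"].map(normalize_chrom)
    keep = ds.manifest.index[~chroms.isin(["chrX", "chrY"])]
    log.info("drop_sex_chromosomes: removed %d of %d probes",
             len(ds.manifest) - len(keep), len(ds.manifest))
    return ds.subset_probes(keep)


def beta_to_m(beta, eps: float = LOGIT_EPS):
    """Base-2 logit transform, M = log2(beta / (1 - beta)), clamped to [eps, 1-eps]."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1 - eps)
    return np.log2(b / (1 - b))


def m_to_beta(m):
    """Inverse logit, beta = 2^M / (2^M + 1), computed overflow-safely."""
    m = np.asarray(m, dtype=float)
    # equivalent to 2**m/(2**m+1) but stable for large |m|
    return 0.5 * (1 + np.tanh(0.5 * math.log(2) * m))


def quantile_normalize(m: MValueMatrix) -> MValueMatrix:
    """Force every sample column onto the common sorted-mean distribution.

    The reference distribution is the row-wise mean of the per-column
    sorted values; each column's values are replaced by the reference
    value at their rank, preserving within-column rank order. Ties share
    the mean of the reference values at the tied rank positions.
    """
    df = m.values
    if df.isna().any().any():
        raise ValueError("quantile normalization requires no missing values")
    if df.shape[1] < 2:
        log.warning("quantile_normalize: single sample, returning input unchanged")
        return m.with_step(df.copy(), "quantile_normalize(identity: 1 sample)")
    arr = df.to_numpy(dtype=float)
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # average the reference over runs of tied input values
        sorted_col = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_col) != 0) + 1
        groups = np.split(np.arange(col.size), boundaries)
        for g in groups:
            if len(g) > 1:
                assigned[order[g]] = ref[g].mean()
        out[:, j] = assigned
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    return m.with_step(result, "quantile_normalize")


def _find_modes(values: np.ndarray, grid_points: int = 512) -> tuple[float, float] | None:
    """Locate the unmethylated (M<0) and methylated (M>0) density modes.

    Returns None when either side lacks enough mass for a stable KDE mode.
    """
    neg = values[values < 0]
    pos = values[values > 0]
    if neg.size < 10 or pos.size < 10:
        return None
    modes = []
    for side in (neg, pos):
        if np.ptp(side) == 0:
            modes.append(float(side[0]))
            continue
        kde = gaussian_kde(side)  # Silverman bandwidth default
        grid = np.linspace(side.min(), side.max(), grid_points)
        modes.append(float(grid[np.argmax(kde(grid))]))
    unmeth, meth = modes
    if unmeth >= 0 or meth <= 0:
        return None
    return unmeth, meth


def peak_correct(m: MValueMatrix, manifest: pd.DataFrame) -> MValueMatrix:
    """Rescale Infinium type-II M values onto the type-I peak positions.

    Per sample, the unmethylated and methylated modes of the type-I and
    type-II M distributions are located by kernel density estimation;
    negative type-II values are scaled by peakI_unmeth/peakII_unmeth and
    positive values by peakI_meth/peakII_meth, mapping the compressed
    type-II peaks onto the type-I scale. Type-I values are unchanged.
    Samples where a stratum is unimodal are left uncorrected with a
    logged warning.
    """
    df = m.values
    design = manifest.loc[df.index, "design_type"]
    is_ii = (design == "II").to_numpy()
    is_i = (design == "I").to_numpy()
    out = df.to_numpy(dtype=float).copy()
    corrected_samples = []
    for j, sample in enumerate(df.columns):
        col = out[:, j]
        modes_i = _find_modes(col[is_i])
        modes_ii = _find_modes(col[is_ii])
        if modes_i is None or modes_ii is None:
            log.warning(
                "peak_correct: mode detection failed for sample %s; skipped", sample
            )
            continue
        scale_unmeth = modes_i[0] / modes_ii[0]
        scale_meth = modes_i[1] / modes_ii[1]
        col_ii = col[is_ii]
        col_ii = np.where(col_ii < 0, col_ii * scale_unmeth, col_ii * scale_meth)
        col[is_ii] = col_ii
        corrected_samples.append(sample)
    result = pd.DataFrame(out, index=df.index, columns=df.columns)
    return m.with_step(
        result, f"peak_correct({len(corrected_samples)}/{df.shape[1]} samples)"
    )


def preprocess_pipeline(
    ds: MethylationDataset,
    *,
    sample_p_thresh: float = 0.05,
    sample_frac: float = 0.90,
    probe_p_thresh: float = 1e-5,
    probe_frac: float = 0.75,
    do_quantile: bool = True,
    do_peak_correct: bool = True,
) -> tuple[MethylationDataset, MValueMatrix]:
    """Run the full QC + normalization chain in the documented order.

    Returns the filtered dataset alongside the normalized M-value matrix
    (the provenance list records each step and the filter removal counts).
    """
    n0 = len(ds.manifest)
    steps = []
    ds = drop_missing_probes(ds)
    steps.append(f"drop_missing_probes: {n0} -> {len(ds.manifest)}")
    n = len(ds.sample_ids)
    ds = drop_failed_samples(ds, sample_p_thresh, sample_frac)
    steps.append(f"drop_failed_samples: {n} -> {len(ds.sample_ids)} samples")
    n = len(ds.manifest)
    ds = drop_failed_probes(ds, probe_p_thresh, probe_frac)
    steps.append(f"drop_failed_probes: {n} -> {len(ds.manifest)}")
    n = len(ds.manifest)
    ds = drop_sex_chromosomes(ds)
    steps.append(f"drop_sex_chromosomes: {n} -> {len(ds.manifest)}")
    m_df = pd.DataFrame(
        beta_to_m(ds.beta.to_numpy(dtype=float)),
        index=ds.beta.index,
        columns=ds.beta.columns,
    )
    m = MValueMatrix(m_df, steps + ["beta_to_m"])
    if do_quantile:
        m = quantile_normalize(m)
    if do_peak_correct:
        m = peak_correct(m, ds.manifest)
    return ds, m
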
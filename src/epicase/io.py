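"""File readers/writers and the end-to-end pipeline runner.

Formats are plain text: the probe manifest is CSV with header
(probe_id, chrom, pos, design_type); beta and detection-p matrices are TSV
with probe ids as row keys and sample ids as columns, missing values
written "NA"; region reports are TSV and BED6 (BED uses 0-based half-open
coordinates, the TSV keeps the 1-based inclusive manifest convention —
both note this in a header comment). Gzipped inputs are accepted
transparently (pandas dispatches on the .gz suffix).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import MethylationDataset, preprocess_pipeline
from .regions import (
    FilterConfig,
    RegionCall,
    call_regions,
    filter_candidates,
    test_probes,
)
from .singlecase import Method

log = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_manifest",
    "read_matrix",
    "write_matrix",
    "read_dataset",
    "write_dataset",
    "write_probe_results",
    "write_regions_tsv",
    "write_regions_bed",
    "load_run_config",
    "run_pipeline",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos", "design_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].head().tolist()
        raise ValueError(f"duplicate probe ids in manifest {path}: {dupes}")
    bad = ~df["design_type"].isin(["I", "II"])
    if bad.any():
        raise ValueError(
            f"manifest {path}: invalid design_type values "
            f"{df.loc[bad, 'design_type'].unique().tolist()}"
        )
    return df.set_index("probe_id")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probes-by-samples TSV; "NA" cells become missing, never 0."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=True)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicate probe ids in matrix {path}: {dupes}")
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        for c in non_numeric:
            bad_rows = df.index[pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()]
            if len(bad_rows):
                raise ValueError(
                    f"non-numeric cell in {path}, column {c!r}, row {bad_rows[0]!r}"
                )
        df = df.apply(pd.to_numeric)
    df.index = df.index.astype(str)
    df.index.name = "probe_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_dataset(
    manifest_path: str | Path,
    beta_path: str | Path,
    detection_p_path: str | Path,
    case: str,
    controls: list[str] | None = None,
) -> MethylationDataset:
    """Load and cross-validate the three input files.

    ``controls=None`` means every non-case sample is a control.
    """
    manifest = read_manifest(manifest_path)
    beta = read_matrix(beta_path)
    detp = read_matrix(detection_p_path)
    if set(beta.columns) != set(detp.columns):
        diff = sorted(set(beta.columns) ^ set(detp.columns))
        raise ValueError(
            f"beta and detection-p sample columns differ: {diff}"
        )
    detp = detp[beta.columns]
    if not beta.index.equals(manifest.index):
        if set(beta.index) != set(manifest.index):
            diff = sorted(set(beta.index) ^ set(manifest.index))[:5]
            raise ValueError(f"probe ids differ between manifest and beta: {diff}")
        beta = beta.loc[manifest.index]
    if not detp.index.equals(manifest.index):
        if set(detp.index) != set(manifest.index):
            diff = sorted(set(detp.index) ^ set(manifest.index))[:5]
            raise ValueError(f"probe ids differ between manifest and detection-p: {diff}")
        detp = detp.loc[manifest.index]
    if case not in beta.columns:
        raise ValueError(f"case sample {case!r} not found in matrix columns")
    if controls is None:
        controls = [s for s in beta.columns if s != case]
    else:
        missing = set(controls) - set(beta.columns)
        if missing:
            raise ValueError(f"control samples absent from matrices: {sorted(missing)}")
    roles = {case: "case", **{c: "control" for c in controls}}
    return MethylationDataset(manifest, beta, detp, roles)


def write_dataset(ds: MethylationDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "manifest": outdir / "manifest.csv",
        "beta": outdir / "beta.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "roles": outdir / "roles.tsv",
    }
    ds.manifest.to_csv(paths["manifest"], index_label="probe_id")
    write_matrix(ds.beta, paths["beta"])
    write_matrix(ds.detection_p, paths["detection_p"])
    pd.Series(ds.roles, name="role").rename_axis("sample_id").to_csv(
        paths["roles"], sep="\t"
    )
    return paths


def write_probe_results(results: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-probe single-case results; pos is 1-based\n")
        results.to_csv(fh, sep="\t", index_label="probe_id")


def write_regions_tsv(regions: list[RegionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# called hypomethylated regions; start/end are 1-based inclusive\n")
        fh.write(
            "chrom\tstart\tend\tk\tfisher_chi2\tfisher_df\tlog10_p\tp_display"
            "\tmean_delta_m\tprobe_ids\n"
        )
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.k}\t{r.fisher_chi2:.4f}\t"
                f"{r.fisher_df}\t{r.log10_p:.4f}\t{r.p_display:.4g}\t"
                f"{r.mean_delta_m:.4f}\t{','.join(r.probe_ids)}\n"
            )


def write_regions_bed(regions: list[RegionCall], path: str | Path) -> None:
    """BED6 export; coordinates converted to 0-based half-open."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            score = int(min(-10.0 * r.log10_p, 1000))
            fh.write(
                f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i + 1}\t{score}\t.\n"
            )


def read_regions_tsv(path: str | Path) -> list[RegionCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        RegionCall(
            chrom=str(row["chrom"]), start=int(row["start"]), end=int(row["end"]),
            probe_ids=tuple(str(row["probe_ids"]).split(",")),
            fisher_chi2=float(row["fisher_chi2"]), fisher_df=int(row["fisher_df"]),
            log10_p=float(row["log10_p"]), p_display=float(row["p_display"]),
            mean_delta_m=float(row["mean_delta_m"]),
        )
        for _, row in df.iterrows()
    ]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; loadable from YAML."""

    manifest: str
    beta: str
    detection_p: str
    case: str
    controls: list[str] | None = None  # None = all other samples
    method: str = "CH"
    outdir: str = "epicase_out"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    do_quantile: bool = True
    do_peak_correct: bool = True

    def __post_init__(self) -> None:
        Method(self.method)  # validate early


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML run config; keyword overrides win over file values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    filt = raw.pop("filter", {})
    if isinstance(filt, dict):
        filt = FilterConfig(**filt)
    return RunConfig(filter=filt, **raw)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute preprocess -> test -> filter -> regions and write all outputs.

    Writes probe-level TSV, region TSV, BED6 and a JSON run log recording
    filter removal counts, effective control n, thresholds and seed.
    Deterministic given identical inputs and seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = read_dataset(cfg.manifest, cfg.beta, cfg.detection_p, cfg.case, cfg.controls)
    n_in = len(ds.manifest)
    ds, m = preprocess_pipeline(
        ds, do_quantile=cfg.do_quantile, do_peak_correct=cfg.do_peak_correct
    )
    results = test_probes(ds, m, cfg.method)
    candidates = filter_candidates(results, cfg.filter)
    regions = call_regions(candidates, results, cfg.filter)

    write_probe_results(results, outdir / "probes.tsv")
    write_regions_tsv(regions, outdir / "regions.tsv")
    write_regions_bed(regions, outdir / "regions.bed")
    run_log = {
        "seed": cfg.seed,
        "method": cfg.method,
        "case": cfg.case,
        "n_controls_effective": len(ds.control_ids),
        "probes_in": n_in,
        "probes_retained": len(ds.manifest),
        "preprocess_steps": m.provenance,
        "filter_config": dataclasses.asdict(cfg.filter),
        "n_candidates": int(len(candidates)),
        "n_regions": len(regions),
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    return {
        "dataset": ds,
        "m_values": m,
        "probe_results": results,
        "candidates": candidates,
        "regions": regions,
        "run_log": run_log,
    }
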
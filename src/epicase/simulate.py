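"""Seeded generator of 450k-style methylation datasets with known truth.

The generator emulates the features of real array data that the pipeline's
filters and tests key on:

* imprinted-like DMRs whose control probes are hemimethylated (beta near
  0.5, M near 0), so they pass the control M in [-1, +1] band;
* a bimodal background of non-imprinted probes (beta near 0.1 or 0.9);
* Infinium type-II dynamic-range compression — type-II M values are shrunk
  toward 0, creating the target that peak correction must undo;
* mosaic case hypomethylation — only a fraction ``effect`` of cells lose
  methylation, so the case beta at a DMR is ``(1-effect)`` times the
  control pattern (effect=1 is complete loss, beta near 0);
* missing beta cells and detection-p failures at configurable rates.

Per-sample noise is applied on the logit (M) scale and transformed back,
which keeps betas inside (0, 1) without truncation artifacts. All
randomness flows through one seeded generator; the same seed reproduces
the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MethylationDataset, beta_to_m, m_to_beta
from .singlecase import Method

__all__ = [
    "DMRSpec",
    "SimulationConfig",
    "TruthSet",
    "simulate",
    "type1_error_experiment",
    "replicate_overlap_experiment",
]


@dataclass(frozen=True)
class DMRSpec:
    """One injected imprinted-like DMR.

    ``effect`` is the mosaic fraction of cells losing methylation in the
    case (0 = none, 1 = complete loss); ``control_beta_mean`` defaults to
    hemimethylation (0.5).
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    effect: float
    label: str
    control_beta_mean: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.effect <= 1):
            raise ValueError(f"effect must lie in [0, 1], got {self.effect}")
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if self.end - self.start + 1 < self.n_probes:
            raise ValueError(
                f"DMR {self.label}: {self.n_probes} probes exceed span "
                f"{self.start}-{self.end}"
            )


def _default_dmrs() -> list[DMRSpec]:
    return [
        DMRSpec("chr6", 144_300_000, 144_301_500, 10, 1.0, "imprinted_locus_A"),
        DMRSpec("chr11", 2_720_000, 2_721_500, 10, 0.5, "imprinted_locus_B"),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults reflect a small batch-matched 450k experiment: 20 controls
    (the control-group size found adequate for single-sample calling),
    ~70% type-II probes with their M values compressed by a factor 0.67,
    per-sample logit-scale noise of 0.2 M units (beta SD near 0.035 at a
    hemimethylated probe), sparse missingness and rare detection failures.
    """

    n_background_probes: int = 1000
    n_controls: int = 20
    dmr_specs: tuple[DMRSpec, ...] = field(default_factory=lambda: tuple(_default_dmrs()))
    beta_noise_sd: float = 0.2  # SD on the logit (M) scale
    typeII_fraction: float = 0.7
    typeII_peak_shrink: float = 0.67
    missing_rate: float = 0.001
    detection_fail_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("typeII_fraction", "missing_rate", "detection_fail_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0 < self.typeII_peak_shrink <= 1):
            raise ValueError("typeII_peak_shrink must lie in (0, 1]")


@dataclass
class TruthSet:
    """Per-probe ground-truth labels and the injected per-DMR effects."""

    probe_labels: pd.Series  # index: probe_id; values: "background" or DMR label
    dmr_effects: pd.DataFrame  # index: label; columns chrom/start/end/effect

    def dmr_spans(self) -> list[tuple[str, int, int]]:
        return [
            (row["chrom"], int(row["start"]), int(row["end"]))
            for _, row in self.dmr_effects.iterrows()
        ]


def simulate(cfg: SimulationConfig) -> tuple[MethylationDataset, TruthSet]:
    """Generate a case + controls methylation dataset with known truth.

    Background probes are scattered across chr1-chr22 far enough apart
    not to form runs; DMR probes are evenly spaced inside their spans.
    Returns the dataset (beta + detection-p + manifest + roles, with the
    case sample named "case") and the matching truth set.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.n_background_probes
    autosomes = [f"chr{i}" for i in range(1, 23)]

    rows = []
    labels = []
    # background: bimodal non-imprinted probes, widely spaced; the modes get
    # per-probe spread and ~10% of probes carry intermediate methylation
    # (shores / partially methylated domains), so the M distribution has
    # mass between the peaks as on a real array
    bg_chroms = rng.choice(autosomes, size=n_bg)
    u = rng.random(n_bg)
    mode_center = np.where(u < 0.45, 0.1, 0.9)
    bg_base = m_to_beta(beta_to_m(mode_center) + rng.normal(0, 0.6, n_bg))
    intermediate = u >= 0.9
    bg_base[intermediate] = rng.uniform(0.25, 0.75, intermediate.sum())
    offset = rng.integers(1_000_000, 2_000_000, size=n_bg)
    counter: dict[str, int] = {}
    for i in range(n_bg):
        c = str(bg_chroms[i])
        counter[c] = counter.get(c, 0) + int(offset[i])
        rows.append((f"bg{i:06d}", c, counter[c], float(bg_base[i]), 0.0))
        labels.append("background")
    # DMR probes: evenly spaced, hemimethylated in controls
    for spec in cfg.dmr_specs:
        pos = np.linspace(spec.start, spec.end, spec.n_probes).astype(int)
        pos = np.unique(pos)
        for j, p in enumerate(pos):
            rows.append(
                (f"{spec.label}_{j:03d}", spec.chrom, int(p),
                 spec.control_beta_mean, spec.effect)
            )
            labels.append(spec.label)

    probe_ids = [r[0] for r in rows]
    manifest = pd.DataFrame(
        {
            "chrom": [r[1] for r in rows],
            "pos": [r[2] for r in rows],
            "design_type": rng.choice(
                ["I", "II"], size=len(rows),
                p=[1 - cfg.typeII_fraction, cfg.typeII_fraction],
            ),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    base_beta = np.array([r[3] for r in rows])
    effects = np.array([r[4] for r in rows])

    sample_ids = ["case"] + [f"ctrl{i:02d}" for i in range(cfg.n_controls)]
    n_samples = len(sample_ids)
    n_probes = len(probe_ids)

    # per-sample target beta: mosaic hypomethylation in the case only
    target = np.tile(base_beta[:, None], (1, n_samples))
    target[:, 0] = base_beta * (1.0 - effects)
    # logit-scale noise, back-transformed
    m_vals = beta_to_m(target) + rng.normal(0, cfg.beta_noise_sd, (n_probes, n_samples))
    # type-II compression toward M = 0 (the peak-correction target)
    is_ii = (manifest["design_type"] == "II").to_numpy()
    m_vals[is_ii, :] *= cfg.typeII_peak_shrink
    beta = m_to_beta(m_vals)

    # detection p: tiny for good measurements, large for injected failures
    detection = rng.uniform(0, 1e-8, (n_probes, n_samples))
    fail = rng.random((n_probes, n_samples)) < cfg.detection_fail_rate
    detection[fail] = rng.uniform(0.05, 1.0, fail.sum())
    # missing beta cells
    miss = rng.random((n_probes, n_samples)) < cfg.missing_rate
    beta[miss] = np.nan

    ds = MethylationDataset(
        manifest=manifest,
        beta=pd.DataFrame(beta, index=manifest.index, columns=sample_ids),
        detection_p=pd.DataFrame(detection, index=manifest.index, columns=sample_ids),
        roles={"case": "case", **{s: "control" for s in sample_ids[1:]}},
    )
    truth = TruthSet(
        probe_labels=pd.Series(labels, index=manifest.index, name="label"),
        dmr_effects=pd.DataFrame(
            {
                "chrom": [s.chrom for s in cfg.dmr_specs],
                "start": [s.start for s in cfg.dmr_specs],
                "end": [s.end for s in cfg.dmr_specs],
                "effect": [s.effect for s in cfg.dmr_specs],
            },
            index=pd.Index([s.label for s in cfg.dmr_specs], name="label"),
        ),
    )
    return ds, truth


def type1_error_experiment(
    n_controls: int,
    n_reps: int,
    method: Method | str = Method.CH,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical type-I error of a single-case test under the null.

    Case and control scores are drawn from one standard normal; returns
    the fraction of replicates with one-tailed (lower for CH/WB, upper
    for OS, i.e. the same direction) p below ``alpha``. Vectorized over
    replicates for speed.
    """
    from scipy import stats

    method = Method(method)
    rng = np.random.default_rng(seed)
    case = rng.normal(size=n_reps)
    ctrl = rng.normal(size=(n_reps, n_controls))
    mean = ctrl.mean(axis=1)
    sd = ctrl.std(ddof=1, axis=1)
    n = n_controls
    if method is Method.CH:
        t = (case - mean) / (sd * np.sqrt((n + 1) / n))
        p = stats.t.cdf(t, n - 1)
    elif method is Method.OS:
        t = (mean - case) / (sd / np.sqrt(n))
        p = stats.t.sf(t, n - 1)  # same (hypomethylation) direction as CH lower tail
    else:
        t = (case - mean) / (sd * np.sqrt(n / (n - 1)))
        p = stats.t.cdf(t, n - 2)
    return float(np.mean(p < alpha))


def replicate_overlap_experiment(
    cfg: SimulationConfig,
    control_pool_size: int,
    group_size: int = 50,
    seed: int = 0,
    filter_cfg=None,
) -> dict:
    """Biological-replicate check: one case against two disjoint control groups.

    The control pool is split into two disjoint groups of ``group_size``;
    the test -> filter -> region pipeline runs twice on the same case, and
    the report gives the per-run candidate-site counts, the intersection
    of candidate probe sets, and the region-level overlap (fraction of
    regions from run 1 overlapped by a run-2 region and vice versa).
    """
    from .preprocess import preprocess_pipeline
    from .regions import FilterConfig, call_regions, filter_candidates, test_probes

    if control_pool_size < 2 * group_size:
        raise ValueError(
            f"control pool ({control_pool_size}) must be >= 2 x group size "
            f"({group_size})"
        )
    filter_cfg = filter_cfg or FilterConfig()
    import dataclasses

    sim_cfg = dataclasses.replace(cfg, n_controls=control_pool_size, seed=seed)
    ds, truth = simulate(sim_cfg)
    rng = np.random.default_rng(seed + 1)
    pool = np.array(ds.control_ids)
    perm = rng.permutation(pool)
    groups = [list(perm[:group_size]), list(perm[group_size: 2 * group_size])]

    runs = []
    for grp in groups:
        sub = ds.subset_samples([ds.case_id] + grp)
        sub, m = preprocess_pipeline(sub)
        results = test_probes(sub, m)
        cand = filter_candidates(results, filter_cfg)
        regions = call_regions(cand, results, filter_cfg)
        runs.append({"candidates": set(cand.index), "regions": regions})

    c1, c2 = runs[0]["candidates"], runs[1]["candidates"]
    r1, r2 = runs[0]["regions"], runs[1]["regions"]

    def overlaps(a, b) -> bool:
        return a.chrom == b.chrom and a.start <= b.end and a.end >= b.start

    frac1 = (
        sum(any(overlaps(a, b) for b in r2) for a in r1) / len(r1) if r1 else float("nan")
    )
    frac2 = (
        sum(any(overlaps(b, a) for a in r1) for b in r2) / len(r2) if r2 else float("nan")
    )
    return {
        "candidates_run1": len(c1),
        "candidates_run2": len(c2),
        "candidates_common": len(c1 & c2),
        "regions_run1": len(r1),
        "regions_run2": len(r2),
        "region_overlap_frac_run1": frac1,
        "region_overlap_frac_run2": frac2,
        "truth_spans": truth.dmr_spans(),
    }
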
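"""Beta-sweep orchestration, statistical endpoints and reader-score report.

``run_sweep`` drives the full chain — phantom, noisy (or noise-free)
acquisition, one reconstruction per beta in the 100..1000 step-50 grid,
quantification — and returns a tidy metrics table. The clinical mode adds
SUV/SNR/CNR per synthetic lesion and supports the recovery-coefficient
partial-volume correction fitted from a phantom sweep.

Statistical endpoints mirror a typical image-quality study: Pearson
correlation of SUVs against beta, a paired t-test between the beta
extremes, and Cohen's kappa for inter-reader agreement on the subjective
scores. The subjective scores themselves ship as a packaged fixture table
(two readers, two lesion-size groups, ten beta values); the report selects
the best-overall-score beta per group and reader.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .acquisition import AcquisitionModel, forward_project, sample_counts
from .geometry import ActivityVolume, GridGeometry
from .phantom import (
    MEDIUM_GROUP,
    SUBCENTIMETER_GROUP,
    PhantomSpec,
    build_clinical_phantom,
    build_phantom,
    default_grid,
    nema_phantom_spec,
)
from .pvc import RCRegression, fit_rc_models, predict_rc
from .quantify import (
    SUVContext,
    background_variability,
    cnr,
    cnr_background_annulus,
    contrast_recovery,
    place_background_rois,
    propagate_voi,
    recovery_coefficient,
    reference_noise_sd,
    segment_voi,
    spherical_kernel,
    suv,
)
from .recon import PenaltyParams, ReconParams, reconstruct

__all__ = [
    "DEFAULT_BETAS",
    "SweepConfig",
    "ReaderScore",
    "run_sweep",
    "apply_pvc_to_metrics",
    "pearson_correlation",
    "paired_t_test",
    "cohens_kappa",
    "overall_score",
    "load_reader_scores",
    "build_report",
    "METRICS_COLUMNS",
]

#: The study's sweep grid: beta 100..1000 in steps of 50 (19 values).
DEFAULT_BETAS: tuple[float, ...] = tuple(float(b) for b in range(100, 1001, 50))

METRICS_COLUMNS = [
    "mode",
    "replicate",
    "beta",
    "object_id",
    "diameter_mm",
    "group",
    "rc_pct",
    "cr_pct",
    "bv_pct",
    "suv_mean",
    "suv_max",
    "suv_peak",
    "snr",
    "cnr",
    "pvc_applied",
    "rc_predicted",
    "extrapolated",
]


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one beta-sweep experiment.

    ``betas`` must be strictly increasing and positive. ``noiseless``
    replaces Poisson sampling by expected counts (one replicate). The
    NEMA mode defaults to three replicates, matching triplicate phantom
    scans; each replicate reuses one sampled sinogram across all betas,
    as a single acquisition reconstructed at every beta.
    """

    mode: str = "nema"  # "nema" | "clinical"
    betas: tuple[float, ...] = DEFAULT_BETAS
    gamma: float = 2.0
    beta_scale: float | None = None
    n_replicates: int = 3
    seed: int = 0
    noiseless: bool = False
    grid_shape: tuple[int, int, int] = (32, 96, 96)
    n_iterations: int = 25
    n_subsets: int = 6
    neighborhood: int = 6
    reference_beta: float = 350.0
    psf_fwhm: float = 4.5
    count_scale: float = 0.03
    lesion_diameters: tuple[float, ...] | None = None
    lesion_contrast: float = 4.0
    suv_context: SUVContext = field(
        default_factory=lambda: SUVContext(60000.0, 60000.0)
    )

    def __post_init__(self) -> None:
        if self.mode not in ("nema", "clinical"):
            raise ValueError("mode must be 'nema' or 'clinical'")
        b = np.asarray(self.betas, dtype=float)
        if b.size == 0 or np.any(b <= 0) or np.any(np.diff(b) <= 0):
            raise ValueError("betas must be strictly increasing and positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def recon_params(self, beta: float) -> ReconParams:
        pen_kwargs = dict(beta=beta, gamma=self.gamma, neighborhood=self.neighborhood)
        if self.beta_scale is not None:
            pen_kwargs["beta_scale"] = self.beta_scale
        return ReconParams(
            penalty=PenaltyParams(**pen_kwargs),
            n_iterations=self.n_iterations,
            n_subsets=self.n_subsets,
        )

    def acquisition(self) -> AcquisitionModel:
        return AcquisitionModel(psf_fwhm=self.psf_fwhm, count_scale=self.count_scale)

    def replicate_seed(self, replicate: int) -> int:
        return int((self.seed * 100003 + 7919 * replicate + 1) % (2**31 - 1))

    def default_lesion_diameters(self) -> tuple[float, ...]:
        """Seven sub-centimeter and sixteen medium lesion diameters, drawn
        uniformly within each group's range (5.7-9.9 and 10-29.4 mm)."""
        rng = np.random.default_rng(self.replicate_seed(997))
        small = rng.uniform(5.7, 9.9, size=7)
        medium = rng.uniform(10.0, 29.4, size=16)
        return tuple(np.round(np.concatenate([small, medium]), 1))


def _all_betas(config: SweepConfig) -> list[float]:
    betas = list(config.betas)
    if config.reference_beta not in betas:
        betas = sorted(set(betas) | {config.reference_beta})
    return betas


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Execute the sweep and return the tidy metrics table.

    Rows: one per (replicate, beta, object); NEMA mode fills the phantom
    metrics (RC/CR/BV), clinical mode the lesion metrics
    (SUVmean/max/peak, SNR, CNR), all uncorrected (``pvc_applied=False``).
    Identical configs (including seed) produce identical tables.
    """
    if config.mode == "nema":
        return _run_nema_sweep(config)
    return _run_clinical_sweep(config)


def _reconstruct_all(counts, grid, config, betas):
    recons = {}
    for b in betas:
        res = reconstruct(counts, grid, config.recon_params(b))
        if not res.converged:
            raise RuntimeError(f"reconstruction at beta {b} failed: {res.status}")
        recons[b] = res.volume
    return recons


def _run_nema_sweep(config: SweepConfig) -> pd.DataFrame:
    grid = GridGeometry(config.grid_shape, (2.8, 2.73, 2.73))
    spec = nema_phantom_spec()
    truth = build_phantom(spec, grid)
    acq = config.acquisition()
    expected = forward_project(truth, acq)
    betas = _all_betas(config)
    roi_sets = {
        s.diameter: place_background_rois(truth, spec, s.diameter) for s in spec.spheres
    }
    n_reps = 1 if config.noiseless else config.n_replicates
    rows = []
    for rep in range(n_reps):
        counts = (
            expected
            if config.noiseless
            else sample_counts(expected, config.replicate_seed(rep))
        )
        recons = _reconstruct_all(counts, grid, config, betas)
        ref_img = recons[config.reference_beta]
        vois = {}
        for s in spec.spheres:
            seed_vox = grid.world_to_voxel(s.center)
            vois[s.diameter] = segment_voi(
                ref_img,
                seed_vox,
                0.42,
                reference_beta=config.reference_beta,
                object_id=s.diameter,
                search_radius_mm=s.radius,
            )
        for b in config.betas:
            img = recons[b]
            for s in spec.spheres:
                voi = propagate_voi(vois[s.diameter], img, b)
                a_m = float(img.values[voi.mask].mean())
                means = roi_sets[s.diameter].roi_means(img)
                a_b = float(means.mean())
                sd_b = float(means.std(ddof=1))
                rows.append(
                    {
                        "mode": "nema",
                        "replicate": rep,
                        "beta": b,
                        "object_id": f"sphere_{s.diameter:g}mm",
                        "diameter_mm": s.diameter,
                        "group": "phantom",
                        "rc_pct": recovery_coefficient(a_m, s.activity),
                        "cr_pct": contrast_recovery(a_m, a_b, spec.contrast),
                        "bv_pct": background_variability(sd_b, a_b),
                        "suv_mean": np.nan,
                        "suv_max": np.nan,
                        "suv_peak": np.nan,
                        "snr": np.nan,
                        "cnr": np.nan,
                        "pvc_applied": False,
                        "rc_predicted": np.nan,
                        "extrapolated": False,
                    }
                )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def _run_clinical_sweep(config: SweepConfig) -> pd.DataFrame:
    grid = GridGeometry(config.grid_shape, (2.8, 2.73, 2.73))
    diameters = config.lesion_diameters or config.default_lesion_diameters()
    truth, catalog, ref_mask = build_clinical_phantom(
        diameters,
        lesion_to_background=config.lesion_contrast,
        grid=grid,
        seed=config.seed,
    )
    lung_mask = np.isclose(truth.values, 1.0)  # background voxels untouched by objects
    acq = config.acquisition()
    expected = forward_project(truth, acq)
    betas = _all_betas(config)
    ctx = config.suv_context
    kernel = spherical_kernel(grid)
    n_reps = 1 if config.noiseless else config.n_replicates
    rows = []
    for rep in range(n_reps):
        counts = (
            expected
            if config.noiseless
            else sample_counts(expected, config.replicate_seed(rep))
        )
        recons = _reconstruct_all(counts, grid, config, betas)
        ref_img = recons[config.reference_beta]
        vois = {}
        annuli = {}
        for lesion in catalog.itertuples():
            center = (lesion.cz_mm, lesion.cy_mm, lesion.cx_mm)
            voi = segment_voi(
                ref_img,
                grid.world_to_voxel(center),
                0.42,
                reference_beta=config.reference_beta,
                object_id=lesion.lesion_id,
                search_radius_mm=lesion.diameter_mm / 2.0 + 2.0,
            )
            vois[lesion.lesion_id] = voi
            annuli[lesion.lesion_id] = cnr_background_annulus(voi, lung_mask)
        for b in config.betas:
            img = recons[b]
            peak_img = ndimage.convolve(img.values, kernel, mode="constant", cval=0.0)
            ref_sd = reference_noise_sd(img, ref_mask, ctx)
            for lesion in catalog.itertuples():
                voi = propagate_voi(vois[lesion.lesion_id], img, b)
                in_voi = img.values[voi.mask]
                s_mean = suv(float(in_voi.mean()), ctx)
                s_max = suv(float(in_voi.max()), ctx)
                s_peak = suv(float(peak_img[voi.mask].max()), ctx)
                shell = annuli[lesion.lesion_id]
                bg_vals = img.values[shell]
                bg_mean = suv(float(bg_vals.mean()), ctx)
                bg_sd = float(np.std([suv(v, ctx) for v in bg_vals], ddof=1))
                rows.append(
                    {
                        "mode": "clinical",
                        "replicate": rep,
                        "beta": b,
                        "object_id": int(lesion.lesion_id),
                        "diameter_mm": lesion.diameter_mm,
                        "group": lesion.group,
                        "rc_pct": np.nan,
                        "cr_pct": np.nan,
                        "bv_pct": np.nan,
                        "suv_mean": s_mean,
                        "suv_max": s_max,
                        "suv_peak": s_peak,
                        "snr": s_max / ref_sd,
                        "cnr": cnr(s_mean, bg_mean, bg_sd),
                        "pvc_applied": False,
                        "rc_predicted": np.nan,
                        "extrapolated": False,
                    }
                )
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def apply_pvc_to_metrics(
    metrics: pd.DataFrame, models: dict[float, RCRegression]
) -> pd.DataFrame:
    """Append PVC-corrected rows to a clinical metrics table.

    Each uncorrected row gains a corrected twin whose SUVs are divided by
    the RC predicted from the row's lesion diameter with the model of the
    matching beta.
    """
    out = [metrics]
    corrected = []
    for row in metrics.itertuples():
        if row.pvc_applied:
            continue
        model = models.get(float(row.beta))
        if model is None:
            raise KeyError(f"no RC model for beta {row.beta}")
        pred = predict_rc(model, row.diameter_mm)
        r = row._asdict()
        r.pop("Index", None)
        r.update(
            suv_mean=row.suv_mean / pred.rc,
            suv_max=row.suv_max / pred.rc,
            suv_peak=row.suv_peak / pred.rc,
            pvc_applied=True,
            rc_predicted=pred.rc,
            extrapolated=pred.extrapolated,
        )
        corrected.append(r)
    out.append(pd.DataFrame(corrected, columns=METRICS_COLUMNS))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# statistics


def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment correlation r and two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(a, b) -> tuple[float, float]:
    """Paired two-sided t-test on matched samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0):
        raise ValueError("zero variance of paired differences: t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def cohens_kappa(r1, r2) -> float:
    """Unweighted Cohen's kappa, scores treated as nominal categories."""
    from sklearn.metrics import cohen_kappa_score

    r1 = list(r1)
    r2 = list(r2)
    if len(r1) != len(r2) or not r1:
        raise ValueError("rating vectors must be non-empty and equal length")
    if len(set(r1)) == 1 and set(r1) == set(r2):
        raise ValueError("kappa undefined: both raters constant and equal")
    # half-point scores are nominal categories: encode before scoring
    cats = {c: i for i, c in enumerate(sorted(set(r1) | set(r2)))}
    return float(cohen_kappa_score([cats[c] for c in r1], [cats[c] for c in r2]))


def overall_score(general: float, sharpness: float, conspicuity: float) -> float:
    """Overall subjective score: exact sum of the three component scores."""
    for name, v in (
        ("general", general),
        ("sharpness", sharpness),
        ("conspicuity", conspicuity),
    ):
        if not (1.0 <= v <= 5.0):
            raise ValueError(f"{name} score {v} outside the 1-5 rating scale")
    return general + sharpness + conspicuity


@dataclass(frozen=True)
class ReaderScore:
    """One reader's component scores for one group x beta cell."""

    group: str
    beta: float
    reader: int
    general_quality: float
    sharpness: float
    conspicuity: float

    def __post_init__(self) -> None:
        for v in (self.general_quality, self.sharpness, self.conspicuity):
            if not (1.0 <= v <= 5.0):
                raise ValueError("component scores must lie in [1, 5]")

    @property
    def overall(self) -> float:
        return overall_score(self.general_quality, self.sharpness, self.conspicuity)


def load_reader_scores() -> pd.DataFrame:
    """Packaged two-reader subjective scores (columns: group, beta, reader,
    general_quality, sharpness, conspicuity, overall)."""
    ref = importlib.resources.files("betapet").joinpath("data/reader_scores.csv")
    with ref.open() as f:
        df = pd.read_csv(f, comment="#")
    mismatch = ~np.isclose(
        df["overall"], df[["general_quality", "sharpness", "conspicuity"]].sum(axis=1)
    )
    if mismatch.any():
        raise ValueError("overall column inconsistent with component sum")
    return df


def best_beta_by_group(scores: pd.DataFrame) -> pd.DataFrame:
    """Highest-overall-score beta per (group, reader); ties -> lowest beta."""
    rows = []
    for (group, reader), g in scores.groupby(["group", "reader"]):
        g = g.sort_values("beta")
        best = g.loc[g["overall"].idxmax()]
        rows.append({"group": group, "reader": reader, "best_beta": float(best["beta"])})
    return pd.DataFrame(rows)


def build_report(
    metrics: pd.DataFrame, scores: pd.DataFrame, out_dir=None
) -> dict:
    """Aggregate the sweep and reader-score endpoints into a report bundle.

    Returns a dict with (depending on the metrics' content): RC/CR/BV
    curves per sphere, SNR/CNR per size group, SUV-vs-beta correlations
    pre/post PVC, the inter-reader kappa values and the
    best-overall-score beta per group. When ``out_dir`` is given, the
    tables are written as CSV and the curves as PNG figures.
    """
    if metrics.empty:
        raise ValueError("metrics table is empty")
    if scores.empty:
        raise ValueError("scores table is empty")
    report: dict = {}

    nema = metrics[metrics["mode"] == "nema"]
    if not nema.empty:
        report["nema_curves"] = (
            nema.groupby(["diameter_mm", "beta"])[["rc_pct", "cr_pct", "bv_pct"]]
            .mean()
            .reset_index()
        )

    clin = metrics[metrics["mode"] == "clinical"]
    if not clin.empty:
        report["snr_cnr_curves"] = (
            clin[~clin["pvc_applied"]]
            .groupby(["group", "beta"])[["snr", "cnr"]]
            .mean()
            .reset_index()
        )
        corr_rows = []
        for (group, applied), g in clin.groupby(["group", "pvc_applied"]):
            curve = g.groupby("beta")[["suv_mean", "suv_max", "suv_peak"]].mean()
            for col in ("suv_mean", "suv_max", "suv_peak"):
                r, p = pearson_correlation(curve.index.to_numpy(), curve[col].to_numpy())
                corr_rows.append(
                    {
                        "group": group,
                        "pvc_applied": applied,
                        "metric": col,
                        "pearson_r": r,
                        "p_value": p,
                    }
                )
        report["suv_beta_correlations"] = pd.DataFrame(corr_rows)

    kappa_rows = []
    pivot = scores.pivot_table(
        index=["group", "beta"],
        columns="reader",
        values=["general_quality", "sharpness", "conspicuity", "overall"],
    )
    for comp in ("general_quality", "sharpness", "conspicuity", "overall"):
        r1 = pivot[comp][1].to_numpy()
        r2 = pivot[comp][2].to_numpy()
        try:
            k = cohens_kappa(list(r1), list(r2))
        except ValueError:
            k = np.nan
        kappa_rows.append({"component": comp, "kappa": k})
    report["reader_kappa"] = pd.DataFrame(kappa_rows)
    report["best_beta"] = best_beta_by_group(scores)

    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir) -> None:
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in report.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"{name}.csv", index=False)
    if "nema_curves" in report:
        fig, axes = plt.subplots(1, 3, figsize=(13, 4))
        for ax, col, title in zip(
            axes, ("rc_pct", "cr_pct", "bv_pct"), ("RC (%)", "CR (%)", "BV (%)")
        ):
            for d, g in report["nema_curves"].groupby("diameter_mm"):
                ax.plot(g["beta"], g[col], marker="o", ms=3, label=f"{d:g} mm")
            ax.set_xlabel("beta")
            ax.set_title(title)
        axes[0].legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "nema_curves.png", dpi=120)
        plt.close(fig)
    if "snr_cnr_curves" in report:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, col in zip(axes, ("snr", "cnr")):
            for grp, g in report["snr_cnr_curves"].groupby("group"):
                ax.plot(g["beta"], g[col], marker="o", ms=3, label=grp)
            ax.set_xlabel("beta")
            ax.set_title(col.upper())
        axes[0].legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "snr_cnr_curves.png", dpi=120)
        plt.close(fig)
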
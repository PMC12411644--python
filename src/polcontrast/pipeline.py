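"""End-to-end pipeline: simulate/ingest -> DOP + Mueller -> mask/registration
-> contrast statistics -> machine-readable outputs and report figures.

Stage order and failure contract: each stage runs inside a named guard; the
first failure raises :class:`StageError` carrying the stage name and a
distinct exit code, and leaves any partial outputs flagged in the run log.

Randomness: everything derives from the single run seed — the scene uses the
seed itself, the Mueller scene ``seed + 1``, and the bootstrap CIs
``seed + 1000`` (circular) and ``seed + 2000`` (linear).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrast as cs
from . import io as pio
from . import polarimetry as pol
from . import segmentation as seg
from . import synthetic as syn

__all__ = ["RunConfig", "StageError", "ResultBundle", "run_pipeline", "render_report"]

log = logging.getLogger("polcontrast")

_STAGE_EXIT = {
    "simulate": 2,
    "ingest": 3,
    "dop": 4,
    "mueller": 5,
    "segment": 6,
    "register": 7,
    "contrast": 8,
    "report": 9,
}


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = _STAGE_EXIT.get(stage, 1)


@dataclass
class RunConfig:
    """Run configuration; YAML files map 1:1 onto these fields."""

    out_dir: str = "polcontrast_out"
    seed: int = 0
    # input paths; when frames_manifest is None the synthetic scene is used
    frames_manifest: str | None = None
    mueller_manifest: str | None = None
    fluorescence: str | None = None
    fiducials: str | None = None
    exclusion_mask: str | None = None
    # synthetic-scene field overrides (see synthetic.SceneConfig)
    scene: dict = field(default_factory=dict)
    # stage parameters
    threshold_fraction: float = 0.95
    outline_thickness: int = 5
    keep_largest: bool = False
    registration_model: str = "similarity"
    bins: int = 80
    roc_step: float = 0.05
    n_boot: int = 300
    run_mueller: bool = True
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResultBundle:
    """Everything downstream reporting needs, in memory."""

    config: RunConfig
    docp: pol.DOPImage | None = None
    dolp: pol.DOPImage | None = None
    mueller: pol.MuellerImage | None = None
    mueller_overlap: np.ndarray | None = None  # 4x4 per-element overlap areas
    mask_pol: seg.RegionMask | None = None
    outline_pol: seg.OutlineImage | None = None
    transform: seg.RegistrationTransform | None = None
    contrast: dict = field(default_factory=dict)
    summary: cs.RegionSummary | None = None
    figures: list = field(default_factory=list)


def _setup_logging(out_dir: Path) -> None:
    if any(isinstance(h, logging.FileHandler) and Path(h.baseFilename).parent == out_dir for h in log.handlers):
        return
    log.setLevel(logging.INFO)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(fmt)
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler) for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        log.addHandler(sh)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise StageError(name, str(exc)) from exc
            log.info("stage %s: done", name)
            return out
        return inner
    return wrap


@_stage("simulate")
def _simulate(config: RunConfig, out: Path):
    scene_cfg = syn.default_scene_config(config.seed, **{k: _tupled(v) for k, v in config.scene.items()})
    truth, mset, fluor = syn.make_dop_scene(scene_cfg)
    frames_dir = out / "frames"
    pio.write_measurement_set(frames_dir, mset)
    pio.write_image(out / "fluorescence.tif", fluor)
    pio.write_fiducials(out / "fiducials.csv", truth.fiducials_fluor, truth.fiducials_pol)
    pio.write_mask(out / "true_mask.png", seg.RegionMask(mask=truth.class_map, frame="polarimetry"))
    mueller_mset = None
    if config.run_mueller:
        m_cfg = dataclasses.replace(scene_cfg, seed=config.seed + 1)
        _, mueller_mset = syn.make_mueller_scene(m_cfg)
        pio.write_measurement_set(out / "mueller_frames", mueller_mset)
    log.info(
        "simulate: %d DOP frames, fluorescence, %d fiducials, tumor pixels=%d",
        len(mset.frames), len(truth.fiducials_pol), int(truth.class_map.sum()),
    )
    return truth, mset, fluor, mueller_mset


def _tupled(value):
    return tuple(value) if isinstance(value, list) else value


@_stage("ingest")
def _ingest(config: RunConfig):
    mset = pio.read_measurement_set(config.frames_manifest)
    if config.fluorescence is None or config.fiducials is None:
        raise ValueError("fluorescence image and fiducials CSV are required with external frames")
    fluor = pio.read_image(config.fluorescence)
    mueller_mset = pio.read_measurement_set(config.mueller_manifest) if config.mueller_manifest else None
    return mset, fluor, mueller_mset


@_stage("dop")
def _dop_stage(config: RunConfig, mset: pol.PolarimetricMeasurementSet, out: Path):
    keys = set(mset.frames)
    circ = [(i, a) for i, a in keys if a in ("R", "L") and i in ("R", "L")]
    if len(circ) != 2:
        raise ValueError("need analyzed R and L frames under one circular incident state")
    inc = circ[0][0]
    docp = pol.signed_docp(mset.frame(inc, "R"), mset.frame(inc, "L"), incident_helicity=inc)

    hv_inc = next((i for i, a in keys if a in ("H", "V") and i in ("H", "V")), None)
    dg_inc = next((i for i, a in keys if a in ("P45", "M45") and i in ("P45", "M45")), None)
    if hv_inc is None or dg_inc is None:
        raise ValueError("need H/V frames under pure H or V incidence and +-45 frames under pure +-45 incidence")
    dolp = pol.signed_dolp(
        mset.frame(hv_inc, "H"), mset.frame(hv_inc, "V"),
        mset.frame(dg_inc, "P45"), mset.frame(dg_inc, "M45"),
        incident_hv=hv_inc, incident_diag=dg_inc,
    )
    total = pol.total_dop_magnitude(dolp, docp)
    pio.write_dop_image(out / "docp.tif", docp)
    pio.write_dop_image(out / "dolp.tif", dolp)
    pio.write_dop_image(out / "dop_total.tif", total)
    log.info(
        "dop: incident (%s, %s, %s); valid pixels circular=%d linear=%d",
        inc, hv_inc, dg_inc, int(docp.valid_mask.sum()), int(dolp.valid_mask.sum()),
    )
    return docp, dolp, total


@_stage("mueller")
def _mueller_stage(mset: pol.PolarimetricMeasurementSet, out: Path):
    mimg = pol.mueller_from_measurements(mset, normalize=True)
    pio.write_image(out / "mueller_m44.tif", mimg.element(4, 4))
    log.info("mueller: reconstructed %s field, valid pixels=%d", mimg.m.shape[:2], int(mimg.valid_mask.sum()))
    return mimg


@_stage("segment")
def _segment_stage(config: RunConfig, fluor: np.ndarray, out: Path):
    mask = seg.threshold_fluorescence(fluor, fraction=config.threshold_fraction, keep_largest=config.keep_largest)
    outline = seg.extract_outline(mask, thickness=config.outline_thickness)
    pio.write_mask(out / "mask_fluorescence.png", mask)
    pio.write_mask(out / "outline_fluorescence.png", outline)
    log.info(
        "segment: fraction=%.3f tumor pixels=%d outline pixels=%d",
        config.threshold_fraction, int(mask.mask.sum()), int(outline.outline.sum()),
    )
    return mask, outline


@_stage("register")
def _register_stage(config: RunConfig, fiducials_path, mask, outline, target_shape, out: Path):
    fluor_pts, pol_pts = pio.read_fiducials(fiducials_path)
    t = seg.estimate_transform(fluor_pts, pol_pts, model=config.registration_model)
    mask_pol = seg.apply_transform(mask, t, target_shape)
    outline_pol = seg.apply_transform(outline, t, target_shape)
    pio.write_mask(out / "mask_polarimetry.png", mask_pol)
    pio.write_mask(out / "outline_polarimetry.png", outline_pol)
    pio.write_json(out / "transform.json", {
        "model": t.model,
        "matrix": t.matrix.tolist(),
        "rotation_rad": t.rotation,
        "scale": t.scale,
        "translation_px": t.translation.tolist(),
        "residual_rmse_px": t.residual_rmse,
        "n_points": int(len(fluor_pts)),
    })
    log.info("register: %s fit on %d points, residual RMSE %.4f px", t.model, len(fluor_pts), t.residual_rmse)
    return t, mask_pol, outline_pol


def _mueller_overlap_table(mimg: pol.MuellerImage, mask: seg.RegionMask, bins: int, exclude) -> np.ndarray:
    table = np.zeros((4, 4))
    for r in range(4):
        for c in range(4):
            elem = pol.DOPImage(
                values=np.clip(mimg.element(r + 1, c + 1), -1.0, 1.0),
                metric="circular",
                valid_mask=mimg.valid_mask,
            )
            h = cs.region_histograms(elem, mask, bins=bins, exclude=exclude)
            table[r, c] = cs.overlap_area(h).overlap_area
    return table


@_stage("contrast")
def _contrast_stage(config: RunConfig, bundle: ResultBundle, out: Path, exclude):
    results = {"parameters": {
        "bins": config.bins, "roc_step": config.roc_step, "n_boot": config.n_boot,
        "seed": config.seed, "threshold_fraction": config.threshold_fraction,
        "outline_thickness": config.outline_thickness,
    }}
    mask = bundle.mask_pol
    for name, dop, ci_seed in (("circular", bundle.docp, config.seed + 1000),
                               ("linear", bundle.dolp, config.seed + 2000)):
        hist = cs.region_histograms(dop, mask, bins=config.bins, exclude=exclude)
        ovl = cs.overlap_area(hist)
        roc = cs.roc_curve(dop, mask, step=config.roc_step, exclude=exclude)
        ci = cs.auc_ci(dop, mask, n_boot=config.n_boot, seed=ci_seed, step=config.roc_step, exclude=exclude)
        mag = pol.DOPImage(values=np.abs(dop.values), metric=dop.metric, valid_mask=dop.valid_mask)
        roc_mag = cs.roc_curve(mag, mask, step=config.roc_step, exclude=exclude)
        results[name] = {
            "auc": roc.auc,
            "auc_ci": list(ci),
            "auc_magnitude": roc_mag.auc,
            "overlap": ovl.overlap_area,
            "overlap_bin_width": ovl.bin_width,
            "n_tumor": hist.n_tumor,
            "n_nontumor": hist.n_nontumor,
        }
        pd.DataFrame({
            "threshold": roc.thresholds,
            "tp": roc.tp, "tn": roc.tn, "fp": roc.fp, "fn": roc.fn,
            "sensitivity": roc.sensitivity, "specificity": roc.specificity,
        }).to_csv(out / f"roc_{name}.csv", index=False)
        bundle.contrast[f"hist_{name}"] = hist
        bundle.contrast[f"roc_{name}"] = roc
        log.info("contrast[%s]: AUC=%.4f CI=(%.4f, %.4f) overlap=%.4f", name, roc.auc, ci[0], ci[1], ovl.overlap_area)

    summary = cs.region_summary(bundle.dolp, bundle.docp, mask, exclude=exclude)
    rows = []
    for metric, classes in summary.stats.items():
        for klass, m in classes.items():
            rows.append({"metric": metric, "class": klass, **m})
    for klass, mean in summary.dop_total.items():
        rows.append({"metric": "dop_total_magnitude", "class": klass, "mean": mean, "sd": np.nan, "n": np.nan})
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
    results["summary"] = {"stats": summary.stats, "dop_total": summary.dop_total}

    if bundle.mueller is not None:
        table = _mueller_overlap_table(bundle.mueller, mask, config.bins, exclude)
        bundle.mueller_overlap = table
        pd.DataFrame(table, index=[f"row{r}" for r in range(1, 5)],
                     columns=[f"col{c}" for c in range(1, 5)]).to_csv(out / "mueller_overlap.csv")
        results["mueller_overlap"] = table.tolist()

    pio.write_json(out / "contrast.json", results)
    return results, summary


def run_pipeline(config: RunConfig) -> ResultBundle:
    """Execute every stage and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    log.info("run: parameters %s", config.to_dict())
    pio.write_json(out / "run_config.json", config.to_dict())

    bundle = ResultBundle(config=config)
    if config.frames_manifest is None:
        truth, mset, fluor, mueller_mset = _simulate(config, out)
        fiducials_path = out / "fiducials.csv"
    else:
        mset, fluor, mueller_mset = _ingest(config)
        fiducials_path = config.fiducials

    bundle.docp, bundle.dolp, _total = _dop_stage(config, mset, out)
    if mueller_mset is not None:
        bundle.mueller = _mueller_stage(mueller_mset, out)

    mask_fluor, outline_fluor = _segment_stage(config, fluor, out)
    bundle.transform, bundle.mask_pol, bundle.outline_pol = _register_stage(
        config, fiducials_path, mask_fluor, outline_fluor, bundle.docp.values.shape, out
    )

    exclude = None
    if config.exclusion_mask:
        exclude = pio.read_image(config.exclusion_mask) > 0.5
    bundle.contrast["results"], bundle.summary = _contrast_stage(config, bundle, out, exclude)

    if config.make_figures:
        bundle.figures = render_report(bundle, out)
    log.info("run: complete, outputs in %s", out)
    return bundle


def render_report(bundle: ResultBundle, out_dir) -> list[Path]:
    """Render the figure set; panels with missing inputs are skipped with a warning."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    figures: list[Path] = []
    results = bundle.contrast.get("results", {})

    def save(fig, name):
        path = out_dir / name
        fig.savefig(path, dpi=110)
        plt.close(fig)
        figures.append(path)

    if bundle.mueller is not None and bundle.mueller_overlap is not None:
        fig, axes = plt.subplots(4, 4, figsize=(10, 10))
        for r in range(4):
            for c in range(4):
                ax = axes[r, c]
                ax.imshow(bundle.mueller.element(r + 1, c + 1), cmap="RdBu_r", vmin=-1, vmax=1)
                ax.set_title(f"M{r+1}{c+1}  ovl={bundle.mueller_overlap[r, c]:.3f}", fontsize=8)
                ax.axis("off")
        fig.suptitle("Normalized Mueller elements with tumor/non-tumor histogram overlap")
        save(fig, "fig_mueller.png")
    else:
        log.warning("report: Mueller panel skipped (stage not run)")

    if bundle.docp is not None and bundle.outline_pol is not None:
        fig, axes = plt.subplots(1, 2, figsize=(11, 5))
        for ax, dop, label in ((axes[0], bundle.docp, "circular"), (axes[1], bundle.dolp, "linear")):
            im = ax.imshow(dop.values, cmap="RdBu_r", vmin=-1, vmax=1)
            overlay = np.zeros((*dop.values.shape, 4))
            overlay[bundle.outline_pol.outline] = (0, 0, 0, 1)
            ax.imshow(overlay)
            ax.set_title(f"signed {label} DOP")
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.8)
        save(fig, "fig_dop.png")

    if "hist_circular" in bundle.contrast:
        fig, axes = plt.subplots(1, 2, figsize=(11, 4))
        for ax, name in ((axes[0], "circular"), (axes[1], "linear")):
            h = bundle.contrast[f"hist_{name}"]
            centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
            ax.fill_between(centers, h.tumor_density, step="mid", alpha=0.5, color="red", label="tumor")
            ax.fill_between(centers, h.nontumor_density, step="mid", alpha=0.5, color="green", label="non-tumor")
            ax.set_title(f"{name}: overlap = {results[name]['overlap']:.4f}")
            ax.set_xlabel(f"signed {name} DOP")
            ax.set_ylabel("density")
            ax.legend()
        save(fig, "fig_histograms.png")

    if "roc_circular" in bundle.contrast:
        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        for name, color in (("circular", "tab:blue"), ("linear", "tab:orange")):
            roc = bundle.contrast[f"roc_{name}"]
            ax.plot(roc.points[:, 0], roc.points[:, 1], "-o", ms=3, color=color,
                    label=f"{name} AUC={results[name]['auc']:.4f}")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        save(fig, "fig_roc.png")

    if bundle.summary is not None and bundle.docp is not None and bundle.mask_pol is not None:
        fig, axes = plt.subplots(1, 2, figsize=(11, 4.5))
        mask = bundle.mask_pol.mask
        for ax, dop, name in ((axes[0], bundle.docp, "circular"), (axes[1], bundle.dolp, "linear")):
            data = [dop.values[dop.valid_mask & mask], dop.values[dop.valid_mask & ~mask]]
            parts = ax.violinplot(data, showmeans=True)
            for body, color in zip(parts["bodies"], ("red", "green")):
                body.set_facecolor(color)
            st = bundle.summary.stats[name]
            for i, klass in enumerate(("tumor", "nontumor")):
                m = st[klass]
                ax.text(i + 1, ax.get_ylim()[1], f"{m['mean']:.3f}\n{m['sd']:.3f}",
                        ha="center", va="top", fontsize=8, fontweight="bold")
            ax.set_xticks([1, 2], ["tumor", "non-tumor"])
            ax.set_title(f"signed {name} DOP")
        tot = bundle.summary.dop_total
        fig.suptitle(f"|DOP_total|: tumor {tot['tumor']:.3f}, non-tumor {tot['nontumor']:.3f}")
        save(fig, "fig_violin.png")

    return figures
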
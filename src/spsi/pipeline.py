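"""End-to-end orchestration: mask -> zonal spectra -> texture -> indices
-> band search -> composite -> trait models.

The library entry points are :func:`process_scene` (one orthomosaic to
per-plot features), :func:`assemble_records` (features + traits to a
modelling table with SI, TI, NDTI_COR and SPSI columns) and
:func:`fit_report` (per-dataset and pooled SLR models with validation
metrics).  :func:`run_pipeline` drives the same steps from files plus a
JSON config and writes CSV/JSON reports with a run manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .composite import band_search, ndti_cor, spsi
from .indices import SI_REGISTRY, SpectralVector, compute_all_sis
from .masking import DEFAULT_T_GREEN, DEFAULT_T_VARI, build_green_mask, mask_summary
from .model import evaluate, fit_slr, partition
from .raster import PlotROI, ReflectanceImage, read_reflectance, read_rois, \
    zonal_mean_table
from .texture import GlcmConfig, TextureStats, texture_image, zonal_texture

__all__ = [
    "SceneFeatures",
    "process_scene",
    "assemble_records",
    "fit_report",
    "run_pipeline",
]


@dataclass
class SceneFeatures:
    """Per-plot products of one scene: green-pixel spectra and texture."""

    label: str
    spectral: pd.DataFrame                    # plot_id, n_pixels, R450..R850
    texture_stats: dict[str, TextureStats]    # plot_id -> zonal texture
    green_fraction: pd.DataFrame              # plot_id, green_fraction


def process_scene(image: ReflectanceImage, rois: Sequence[PlotROI],
                  label: str = "",
                  t_green: float = DEFAULT_T_GREEN,
                  t_vari: float = DEFAULT_T_VARI,
                  glcm: GlcmConfig | None = None) -> SceneFeatures:
    """Mask background, then extract zonal green-pixel spectra and texture."""
    mask = build_green_mask(image, t_green, t_vari)
    glcm = glcm or GlcmConfig(masked=True)
    if not glcm.masked:
        cube = texture_image(image, None, glcm)
    else:
        cube = texture_image(image, mask, glcm)
    spectral = zonal_mean_table(image, list(rois), extra_valid=mask.mask)
    stats = {roi.plot_id: zonal_texture(cube, roi) for roi in rois}
    gf = pd.DataFrame(
        {"plot_id": [r.plot_id for r in rois],
         "green_fraction": [mask_summary(mask, r, image) for r in rois]})
    return SceneFeatures(label, spectral, stats, gf)


def _spectral_vector(row: pd.Series) -> SpectralVector:
    values = {float(col[1:]): row[col] for col in row.index
              if col.startswith("R") and col[1:].isdigit()}
    return SpectralVector(values, plot_id=str(row["plot_id"]),
                          n_pixels=int(row.get("n_pixels", 1)))


def assemble_records(features: Sequence[SceneFeatures], truth: pd.DataFrame,
                     si_opt: str = "DATT",
                     ndti_pair: tuple[float, float] = (850.0, 730.0),
                     ti_forms: Sequence[tuple[str, str]] = (("NDRE", "MEA"),),
                     ) -> pd.DataFrame:
    """Join features with traits and derive all index columns per plot.

    Adds every registered spectral index, the requested texture indices
    (``TI_<form>_<feature>`` columns), ``NDTI_COR`` for ``ndti_pair`` and
    ``SPSI = si_opt + NDTI_COR``.
    """
    from .composite import compute_ti

    rows = []
    for feat in features:
        for _, srow in feat.spectral.iterrows():
            pid = str(srow["plot_id"])
            rec: dict = {"plot_id": pid, "dataset_label": feat.label}
            rec.update(compute_all_sis(_spectral_vector(srow)))
            stats = feat.texture_stats[pid]
            for form, texfeat in ti_forms:
                rec[f"TI_{form}_{texfeat}"] = compute_ti(form, texfeat, stats).value
            rec["NDTI_COR"] = ndti_cor(stats, *ndti_pair)
            rec["SPSI"] = spsi(rec[si_opt], rec["NDTI_COR"])
            rows.append(rec)
    df = pd.DataFrame(rows)
    merged = df.merge(truth[["plot_id", "pnpa"]], on="plot_id", how="inner")
    if len(merged) < len(df):
        missing = set(df.plot_id) - set(merged.plot_id)
        raise ValueError(f"plots without trait values: {sorted(missing)[:5]} ...")
    return merged


def check_sign_consistency(records: pd.DataFrame, si_opt: str = "DATT",
                           ndti_col: str = "NDTI_COR",
                           trait: str = "pnpa") -> bool:
    """True iff the SI-trait and NDTI-trait correlations share a sign."""
    sub = records[[si_opt, ndti_col, trait]].dropna()
    r_si = np.corrcoef(sub[si_opt], sub[trait])[0, 1]
    r_ti = np.corrcoef(sub[ndti_col], sub[trait])[0, 1]
    return bool(np.sign(r_si) == np.sign(r_ti))


def fit_report(records: pd.DataFrame, indices: Sequence[str],
               fraction: float = 2.0 / 3.0, seed: int = 0,
               trait: str = "pnpa") -> pd.DataFrame:
    """Per-dataset and pooled SLR models with validation metrics.

    One stratified calibration/validation split (by dataset label) is drawn
    once and reused for every index and grouping, as when several indices
    are compared on a common partition.
    """
    cal, val = partition(records, fraction, seed)
    groups: list[tuple[str, pd.DataFrame, pd.DataFrame]] = [
        ("pooled", cal, val)]
    for label in sorted(records["dataset_label"].unique()):
        groups.append((label, cal[cal.dataset_label == label],
                       val[val.dataset_label == label]))
    rows = []
    for index in indices:
        for name, c, v in groups:
            sub_c = c[[index, trait]].dropna()
            sub_v = v[[index, trait]].dropna()
            if len(sub_c) < 3 or np.ptp(sub_c[index].to_numpy()) == 0:
                continue
            m = fit_slr(sub_c[index], sub_c[trait], index)
            met = evaluate(m, sub_v[index], sub_v[trait]) if len(sub_v) else None
            rows.append({
                "index": index, "dataset": name,
                "slope": m.slope, "intercept": m.intercept,
                "r2_cal": m.r2_cal, "p_slope": m.pvalue, "n_cal": m.n_cal,
                "r2_v": met.r2_v if met else float("nan"),
                "rmse": met.rmse if met else float("nan"),
                "rrmse": met.rrmse if met else float("nan"),
                "n_val": met.n_val if met else 0,
            })
    return pd.DataFrame(rows)


def run_band_search(features: Sequence[SceneFeatures],
                    truth: pd.DataFrame):
    """Exhaustive NDTI_COR pair search over the pooled plots."""
    trait_of = dict(zip(truth.plot_id.astype(str), truth.pnpa))
    plots = [(stats, trait_of[pid])
             for feat in features
             for pid, stats in feat.texture_stats.items()]
    return band_search(plots)


# ---------------------------------------------------------------------------
# file-driven pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the full pipeline from a JSON config; returns the manifest.

    Config keys: ``scenes`` (list of {label, raster, rois, t_green,
    t_vari}), ``traits`` (CSV with plot_id, pnpa), ``si_opt``,
    ``ndti_pair``, ``band_search`` (bool), ``fraction``, ``seed``, and
    optional ``glcm`` overrides.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    glcm = GlcmConfig(masked=True, **config.get("glcm", {}))
    truth = pd.read_csv(config["traits"], dtype={"plot_id": str})
    features = []
    for sc in config["scenes"]:
        image = read_reflectance(sc["raster"])
        rois = read_rois(sc["rois"])
        features.append(process_scene(
            image, rois, sc.get("label", ""),
            sc.get("t_green", DEFAULT_T_GREEN),
            sc.get("t_vari", DEFAULT_T_VARI), glcm))

    si_opt = config.get("si_opt", "DATT")
    ndti_pair = tuple(config.get("ndti_pair", (850.0, 730.0)))

    manifest: dict = {
        "version": _version, "seed": config.get("seed", 0),
        "si_opt": si_opt, "ndti_pair": list(ndti_pair),
        "thresholds": {sc.get("label", ""): [sc.get("t_green", DEFAULT_T_GREEN),
                                             sc.get("t_vari", DEFAULT_T_VARI)]
                       for sc in config["scenes"]},
    }

    if config.get("band_search", False):
        result = run_band_search(features, truth)
        pd.DataFrame(result.r2, index=result.wavelengths,
                     columns=result.wavelengths).to_csv(outdir / "band_search_r2.csv")
        manifest["best_positive"] = list(result.best_positive or ())
        manifest["best_negative"] = list(result.best_negative or ())
        if config.get("use_search_pair", False) and result.best_positive:
            ndti_pair = result.best_positive
            manifest["ndti_pair"] = list(ndti_pair)

    records = assemble_records(features, truth, si_opt, ndti_pair)
    manifest["sign_consistent"] = check_sign_consistency(records, si_opt)
    records.to_csv(outdir / "plot_features.csv", index=False)

    indices = config.get("indices", [si_opt, "TI_NDRE_MEA", "NDTI_COR", "SPSI"])
    report = fit_report(records, indices,
                        config.get("fraction", 2.0 / 3.0),
                        config.get("seed", 0))
    report.to_csv(outdir / "model_report.csv", index=False)
    manifest["n_plots"] = int(len(records))
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
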
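import numpy as np
import pytest

from spsi.model import fit_slr
from spsi.pipeline import assemble_records, process_scene, run_band_search
from spsi.synthetic import SceneConfig, generate_experiment_pair, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 12-plot scene, enough to exercise masking/zonal/texture stages."""
    cfg = SceneConfig(seed=7)
    return generate_scene(cfg, "VE", n_plots=12, seed=7)


@pytest.fixture(scope="session")
def experiment(small_scene):
    """One full two-experiment dataset plus its per-plot record table."""
    cfg = SceneConfig(seed=11)
    ve, se, pooled = generate_experiment_pair(cfg)
    fv = process_scene(ve.image, ve.rois, "VE")
    fs = process_scene(se.image, se.rois, "SE")
    records = assemble_records([fv, fs], pooled)
    return {"ve": ve, "se": se, "pooled": pooled,
            "features": [fv, fs], "records": records}


def _stratification_gain(records, column):
    """R2 gain of per-dataset regression lines over the single pooled line,
    both evaluated on the pooled samples (combined SSE / pooled SST)."""
    sub = records[[column, "pnpa", "dataset_label"]].dropna()
    y = sub.pnpa.to_numpy()
    x = sub[column].to_numpy()
    pooled_fit = fit_slr(x, y)
    sse_pooled = float(((y - pooled_fit.predict(x)) ** 2).sum())
    sse_groups = 0.0
    for _, grp in sub.groupby("dataset_label"):
        m = fit_slr(grp[column], grp.pnpa)
        sse_groups += float(
            ((grp.pnpa.to_numpy() - m.predict(grp[column].to_numpy())) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return sse_pooled / sst - sse_groups / sst


def _pooled_r2(records, column):
    sub = records[[column, "pnpa"]].dropna()
    r = np.corrcoef(sub[column], sub.pnpa)[0, 1]
    return float(r * r)


@pytest.fixture(scope="session")
def seed_sweep():
    """Fifty seeded end-to-end replicates of the two-experiment study.

    For each seed: generate both scenes, run the masked texture pipeline,
    the exhaustive band search and the pooled index regressions; collect
    the quantities the composite-index claims are about.
    """
    rows = []
    for seed in range(1, 51):
        cfg = SceneConfig(seed=seed)
        ve, se, pooled = generate_experiment_pair(cfg)
        fv = process_scene(ve.image, ve.rois, "VE")
        fs = process_scene(se.image, se.rois, "SE")
        records = assemble_records([fv, fs], pooled)
        search = run_band_search([fv, fs], pooled)
        rows.append({
            "seed": seed,
            "best_positive": search.best_positive,
            "best_negative": search.best_negative,
            "r2_datt": _pooled_r2(records, "DATT"),
            "r2_ndti": _pooled_r2(records, "NDTI_COR"),
            "r2_spsi": _pooled_r2(records, "SPSI"),
            "mea_stratification": _stratification_gain(records, "TI_NDRE_MEA"),
            "ndti_stratification": _stratification_gain(records, "NDTI_COR"),
        })
    return rows
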
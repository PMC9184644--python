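"""End-to-end orchestration of the empirical and model analyses.

The empirical pipeline mirrors an MEG-style resting-state analysis on the
synthetic cohort: Welch spectra per region, periodic/aperiodic model fits,
subject-level peak alpha frequency, band-limited PLV/PLI with a
subject-specific alpha band, Pearson age trends, and epoch-shuffle
surrogate significance for the subject-specific band.

The model pipeline runs the whole-brain analysis: natural frequencies from
connectome node strengths, a (K, v) sweep of the delayed Kuramoto network,
metastable-regime delineation, iso-PLV contours, frequency depression along
them, and an Ott-Antonsen agreement tier for the all-to-all reference
network.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import (connectome as cx, kuramoto, oa_theory, phase_locking as pl,
               spectral, sweep as sw, synthetic_data as synth)

logger = logging.getLogger("synchrocomp")

__all__ = ["run_empirical_pipeline", "run_model_pipeline", "config_hash"]


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_empirical_pipeline(cohort_spec: synth.CohortSpec | None = None,
                           surrogate_subjects: int = 5,
                           n_surrogates: int = 100,
                           out_dir: str | Path | None = None) -> dict:
    """Synthetic cohort -> PAF -> bands -> locking -> age trends.

    Returns a dict with the per-subject table, Pearson trend table,
    subject-specific-band surrogate p-values, and provenance. Subjects
    whose spectra yield no alpha peak are dropped with a logged reason;
    more than 50% drops is an error.
    """
    spec = cohort_spec or synth.CohortSpec()
    cfg = asdict(spec)
    t0 = _stage("generate cohort")
    cohort = synth.make_cohort(spec)
    logger.info("cohort of %d subjects in %.1f s", len(cohort), time.perf_counter() - t0)

    t0 = _stage("PAF estimation and phase locking")
    rows, dropped = [], []
    locking_by_subject = {}
    for rec in cohort:
        spectra = [spectral.welch_psd(rec.signals.data[ch], spec.fs,
                                      window_length=spec.epoch_length)
                   for ch in range(rec.signals.n_channels)]
        try:
            est = spectral.subject_paf(spectra)
        except ValueError as exc:
            logger.warning("dropping %s: %s", rec.subject_id, exc)
            dropped.append(rec.subject_id)
            continue
        bands = pl.define_bands(est.subject_mean)
        lock = pl.epoch_locking(rec.signals, bands)
        locking_by_subject[rec.subject_id] = (rec, bands, lock)
        row = dict(subject_id=rec.subject_id, age=rec.age,
                   true_paf=rec.true_paf, paf=est.subject_mean,
                   paf_missing_fraction=est.missing_fraction)
        for band in ("LA", "UA", "SSA"):
            row[f"plv_{band}"] = lock.mean_plv[band]
            row[f"pli_{band}"] = lock.mean_pli[band]
        rows.append(row)
    if len(rows) < 0.5 * len(cohort):
        raise RuntimeError(f"more than half the cohort failed PAF extraction "
                           f"({len(dropped)}/{len(cohort)} dropped)")
    table = pd.DataFrame(rows)
    logger.info("estimated %d subjects in %.1f s", len(table), time.perf_counter() - t0)

    t0 = _stage("age trends")
    trends = pl.cohort_locking_trends(table)

    t0 = _stage("SSA surrogates")
    surro_rows = []
    for i, (rec, bands, _) in enumerate(
            list(locking_by_subject.values())[:surrogate_subjects]):
        for stat in ("plv", "pli"):
            res = pl.surrogate_null(rec.signals, bands.SSA, statistic=stat,
                                    n_surrogates=n_surrogates,
                                    seed=spec.seed * 1000 + i)
            surro_rows.append(dict(subject_id=rec.subject_id, statistic=stat,
                                   observed=res.observed,
                                   null_mean=float(res.null_values.mean()),
                                   p_value=res.p_value))
    surrogates = pd.DataFrame(surro_rows)

    report = dict(subjects=table, trends=trends, surrogates=surrogates,
                  dropped=dropped,
                  provenance=dict(config=cfg, config_hash=config_hash(cfg)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "subjects.tsv", sep="\t", index=False)
        trends.to_csv(out / "trends.tsv", sep="\t", index=False)
        surrogates.to_csv(out / "surrogates.tsv", sep="\t", index=False)
        (out / "empirical_summary.json").write_text(json.dumps(dict(
            config=cfg, config_hash=config_hash(cfg), dropped=dropped,
            n_subjects=len(table),
            trends={r.variable: dict(r=r.r, p=r.p)
                    for r in trends.itertuples()}), indent=2, default=str))
    return report


def run_model_pipeline(connectome_spec: synth.SyntheticConnectomeSpec | None = None,
                       connectome: cx.Connectome | None = None,
                       K_values=None, v_values=None,
                       plv_levels=(0.2, 0.3, 0.4),
                       d: float = 3.0, duration: float = 30.0,
                       transient: float = 10.0, replicates: int = 3,
                       oa_check: bool = True, seed: int = 0,
                       out_dir: str | Path | None = None) -> dict:
    """Connectome -> (K, v) sweep -> isolines -> compensation report.

    Defaults: a 32-node synthetic connectome, K geometric over 1.5 decades,
    v linear on 1-30 m/s, 8 x 8 grid, 3 replicates per cell.
    """
    if connectome is None:
        connectome = synth.make_synthetic_connectome(
            connectome_spec or synth.SyntheticConnectomeSpec(n_nodes=32, seed=seed))
    freqs = cx.assign_natural_frequencies(cx.node_strengths(connectome))
    if K_values is None:
        K_values = np.geomspace(1.0, 10 ** 1.5, 8)
    if v_values is None:
        v_values = np.linspace(1.0, 30.0, 8)

    t0 = _stage("grid sweep")
    grid = sw.grid_sweep(connectome, freqs, K_values, v_values, d=d,
                         duration=duration, transient=transient,
                         replicates=replicates, seed=seed)
    logger.info("sweep done in %.1f s", time.perf_counter() - t0)

    mask, mixture = sw.metastable_regime(grid, seed=seed)
    isolines = {}
    for level in plv_levels:
        path = sw.extract_isoline(grid, "plv", level)
        if path.v.size >= 3:
            isolines[level] = sw.frequency_along_isoline(grid, path)

    oa_table = None
    if oa_check:
        t0 = _stage("OA agreement tier")
        spec = kuramoto.LorentzianSpec(mu=10.0, gamma=1.0)
        oa_table = oa_theory.compare_sim_to_theory(
            [3.0, 6.0], [0.0, 0.010], spec, n=1000, seed=seed)

    cfg = dict(n_nodes=connectome.n_nodes, K_values=list(map(float, K_values)),
               v_values=list(map(float, v_values)), d=d, duration=duration,
               transient=transient, replicates=replicates, seed=seed,
               plv_levels=list(plv_levels))
    report = dict(grid=grid, metastable_mask=mask, mixture=mixture,
                  isolines=isolines, oa_table=oa_table,
                  provenance=dict(config=cfg, config_hash=config_hash(cfg)))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, arr in [("mean_frequency", grid.mean_frequency),
                          ("mean_plv", grid.mean_plv),
                          ("metastability", grid.metastability)]:
            pd.DataFrame(arr, index=grid.K_values, columns=grid.v_values) \
                .to_csv(out / f"sweep_{name}.tsv", sep="\t")
        summary = dict(config=cfg, config_hash=config_hash(cfg),
                       mixture={k: np.asarray(v).tolist() if not np.isscalar(v) else v
                                for k, v in mixture.items()},
                       isolines={str(lv): dict(spearman_rho=r["spearman_rho"],
                                               frequency_drop=r["frequency_drop"])
                                 for lv, r in isolines.items()})
        (out / "model_summary.json").write_text(json.dumps(summary, indent=2,
                                                           default=str))
        for lv, r in isolines.items():
            r["profile"].to_csv(out / f"isoline_plv_{lv:g}.tsv", sep="\t",
                                index=False)
        if oa_table is not None:
            oa_table.to_csv(out / "oa_agreement.tsv", sep="\t", index=False)
    return report
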
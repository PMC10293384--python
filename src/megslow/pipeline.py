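"""End-to-end orchestration: simulate -> measures -> statistics -> CSV reports.

This module glues the library layers together the way a study analysis
would run them: generate (or load) per-subject-visit ROI recordings, reduce
each to whole-brain spectral and connectivity measures (cortical and
subcortical averages), merge with the clinical table, and fit the full
battery of statistical models.  Everything is driven by a flat config
mapping (YAML on disk for the CLI) plus a seed, and all outputs are plain
CSV/JSON so a run is diffable; one config + seed gives identical files.

Recordings travel as NumPy ``.npz`` containers with keys ``data``
(regions x samples), ``sample_rate``, ``subject`` and ``visit``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .atlas import RegionAtlas, load_atlas
from .connectivity import aec_matrix, roi_profile
from .preprocess import (
    BAND_BY_NAME,
    CANONICAL_BANDS,
    RoiRecording,
    bandpass,
    downsample,
    epoch,
)
from .spectral import (
    epoch_spectra,
    normalize_spectrum,
    peak_frequency,
    relative_band_power,
    summarize_regions,
)
from .stats import (
    fit_baseline_group_model,
    fit_clinical_association,
    fit_interaction_model,
    fit_progression_model,
    permutation_connection_test,
)
from .synthetic import (
    ClinicalModel,
    CohortDesign,
    CouplingSpec,
    simulate_cohort,
)

SPECTRAL_MEASURES = tuple(
    [f"rel_power_{b.name}" for b in CANONICAL_BANDS] + ["peak_frequency"]
)


# ---------------------------------------------------------------------------
# recording I/O


def write_recording(rec: RoiRecording, path: str | Path) -> None:
    np.savez(
        path,
        data=rec.data,
        sample_rate=rec.sample_rate,
        subject=rec.subject,
        visit=rec.visit,
    )


def read_recording(path: str | Path) -> RoiRecording:
    with np.load(path, allow_pickle=False) as z:
        return RoiRecording(
            subject=str(z["subject"]),
            visit=str(z["visit"]),
            sample_rate=float(z["sample_rate"]),
            data=np.asarray(z["data"], dtype=float),
        )


def read_recordings(directory: str | Path) -> list[RoiRecording]:
    paths = sorted(Path(directory).glob("*.npz"))
    if not paths:
        raise FileNotFoundError(f"no .npz recordings under {directory}")
    return [read_recording(p) for p in paths]


# ---------------------------------------------------------------------------
# measure reduction


def subject_measures(
    rec: RoiRecording,
    atlas: RegionAtlas,
    epoch_length: int = 4096,
    n_epochs: int | None = 10,
    connectivity_bands: Sequence[str] = (),
) -> dict[str, float]:
    """Whole-brain (cortical/subcortical averaged) measures for one recording."""
    es = epoch(rec, epoch_length=epoch_length, n_epochs=n_epochs)
    ss = epoch_spectra(es)
    bp = relative_band_power(ss)
    row: dict[str, float] = {"subject": rec.subject, "visit": rec.visit}
    for k, name in enumerate(bp.band_names):
        s = summarize_regions(bp.relative_power[:, k], atlas)
        row[f"rel_power_{name}_cortical"] = s.cortical_mean
        row[f"rel_power_{name}_subcortical"] = s.subcortical_mean
    s = summarize_regions(bp.peak_frequency, atlas)
    row["peak_frequency_cortical"] = s.cortical_mean
    row["peak_frequency_subcortical"] = s.subcortical_mean
    for name in connectivity_bands:
        cm = aec_matrix(bandpass(es, BAND_BY_NAME[name]))
        s = summarize_regions(roi_profile(cm).values, atlas)
        row[f"aecc_{name}_cortical"] = s.cortical_mean
        row[f"aecc_{name}_subcortical"] = s.subcortical_mean
    return row


def compute_measures(
    recordings: Iterable[RoiRecording],
    atlas: RegionAtlas,
    epoch_length: int = 4096,
    n_epochs: int | None = 10,
    connectivity_bands: Sequence[str] = (),
) -> pd.DataFrame:
    """Per subject-visit measure table over a collection of recordings."""
    rows = [
        subject_measures(
            rec, atlas,
            epoch_length=epoch_length,
            n_epochs=n_epochs,
            connectivity_bands=connectivity_bands,
        )
        for rec in recordings
    ]
    return pd.DataFrame(rows)


def merge_measures(
    cohort: pd.DataFrame, measures: pd.DataFrame
) -> pd.DataFrame:
    return cohort.merge(measures, on=["subject", "visit"], how="left")


def band_matrices(
    recordings: Iterable[RoiRecording],
    band_name: str,
    epoch_length: int = 4096,
    n_epochs: int | None = 10,
):
    """AEC-c matrices (plus subject/visit keys) for one band."""
    out = []
    for rec in recordings:
        es = epoch(rec, epoch_length=epoch_length, n_epochs=n_epochs)
        cm = aec_matrix(bandpass(es, BAND_BY_NAME[band_name]))
        out.append((rec.subject, rec.visit, cm))
    return out


# ---------------------------------------------------------------------------
# configuration


DEFAULT_CONFIG: dict = {
    "cohort": {},            # overrides for CohortDesign fields
    "downsample_factor": 1,  # applied to recordings before epoching
    "epoch_length": 4096,
    "n_epochs": 10,
    "connectivity_bands": ["theta", "alpha2"],
    "n_permutations": 2000,
    "write_matrices": False,
}


def apply_downsampling(
    cfg: Mapping, recordings: Sequence[RoiRecording]
) -> list[RoiRecording]:
    factor = int(cfg.get("downsample_factor", 1))
    if factor == 1:
        return list(recordings)
    return [downsample(rec, factor) for rec in recordings]


def load_config(path: str | Path | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if key == "cohort" and isinstance(val, Mapping):
                cfg["cohort"].update(val)
            else:
                cfg[key] = val
    return cfg


def design_from_config(cfg: Mapping, seed: int) -> CohortDesign:
    kwargs = dict(cfg.get("cohort", {}))
    kwargs["seed"] = seed
    if "clinical_model" in kwargs and isinstance(kwargs["clinical_model"], Mapping):
        kwargs["clinical_model"] = ClinicalModel(**kwargs["clinical_model"])
    if "couplings" in kwargs:
        kwargs["couplings"] = tuple(
            CouplingSpec(
                (int(c["i"]), int(c["j"])),
                BAND_BY_NAME[c["band"]],
                float(c["strength"]),
            )
            for c in kwargs["couplings"]
        )
    if "visits" in kwargs:
        kwargs["visits"] = tuple(kwargs["visits"])
    # keep recording geometry consistent with the analysis settings
    kwargs.setdefault("epoch_length", cfg.get("epoch_length", 4096))
    kwargs.setdefault("n_epochs", cfg.get("n_epochs", 10))
    return CohortDesign(**kwargs)


# ---------------------------------------------------------------------------
# pipeline stages (each maps to one CLI command)


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def stage_simulate(cfg: Mapping, seed: int, outdir: Path) -> list[RoiRecording]:
    """Generate a cohort; write recordings, cohort table and ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    rec_dir = outdir / "recordings"
    rec_dir.mkdir(exist_ok=True)
    design = design_from_config(cfg, seed)
    recordings, cohort, truth = simulate_cohort(design)
    for rec in recordings:
        write_recording(rec, rec_dir / f"{rec.subject}_{rec.visit}.npz")
    _float_csv(cohort, outdir / "cohort.csv")
    _float_csv(truth.table, outdir / "ground_truth.csv")
    meta = {
        "design": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(design).items()
            if k not in ("couplings", "clinical_model")
        },
        "clinical_model": dataclasses.asdict(design.clinical_model),
        "couplings": [
            {"i": c.region_pair[0], "j": c.region_pair[1],
             "band": c.band.name, "strength": c.strength}
            for c in design.couplings
        ],
    }
    (outdir / "design.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return recordings


def stage_power(
    cfg: Mapping,
    recordings: Sequence[RoiRecording],
    atlas: RegionAtlas,
    outdir: Path,
) -> pd.DataFrame:
    """Spectral measures: tidy region-level tables plus whole-brain summaries."""
    outdir.mkdir(parents=True, exist_ok=True)
    L, n_ep = cfg["epoch_length"], cfg["n_epochs"]
    region_rows = []
    peak_rows = []
    spectra_rows = []
    for rec in recordings:
        es = epoch(rec, epoch_length=L, n_epochs=n_ep)
        ss = epoch_spectra(es)
        bp = relative_band_power(ss)
        for r, label in enumerate(atlas.labels):
            for k, name in enumerate(bp.band_names):
                region_rows.append(
                    {
                        "subject": rec.subject, "visit": rec.visit,
                        "region": label, "band": name,
                        "relative_power": bp.relative_power[r, k],
                    }
                )
            peak_rows.append(
                {
                    "subject": rec.subject, "visit": rec.visit,
                    "region": label,
                    "peak_frequency": bp.peak_frequency[r],
                }
            )
        norm = normalize_spectrum(ss)
        spectra_rows.append(
            pd.DataFrame(
                {
                    "subject": rec.subject, "visit": rec.visit,
                    "frequency": norm.frequencies,
                    "mean_power": norm.power.mean(axis=0),
                }
            )
        )
    _float_csv(pd.DataFrame(region_rows), outdir / "region_relative_power.csv")
    _float_csv(pd.DataFrame(peak_rows), outdir / "region_peak_frequency.csv")
    spectra = pd.concat(spectra_rows, ignore_index=True)
    group_spec = (
        spectra.groupby(["visit", "frequency"], as_index=False)["mean_power"]
        .mean()
    )
    _float_csv(group_spec, outdir / "group_spectra.csv")
    measures = compute_measures(
        recordings, atlas, epoch_length=L, n_epochs=n_ep,
        connectivity_bands=(),
    )
    _float_csv(measures, outdir / "spectral_measures.csv")
    return measures


def stage_connectivity(
    cfg: Mapping,
    recordings: Sequence[RoiRecording],
    atlas: RegionAtlas,
    outdir: Path,
) -> tuple[pd.DataFrame, dict]:
    """AEC-c profiles per band; optional per-subject matrix CSVs."""
    outdir.mkdir(parents=True, exist_ok=True)
    L, n_ep = cfg["epoch_length"], cfg["n_epochs"]
    profile_rows = []
    summary_rows: dict[tuple, dict] = {}
    matrices: dict[str, list] = {}
    mat_dir = outdir / "matrices"
    for name in cfg["connectivity_bands"]:
        matrices[name] = band_matrices(
            recordings, name, epoch_length=L, n_epochs=n_ep
        )
        for subject, visit, cm in matrices[name]:
            prof = roi_profile(cm)
            for r, label in enumerate(atlas.labels):
                profile_rows.append(
                    {
                        "subject": subject, "visit": visit, "band": name,
                        "region": label, "aecc": prof.values[r],
                    }
                )
            s = summarize_regions(prof.values, atlas)
            key = (subject, visit)
            summary_rows.setdefault(key, {"subject": subject, "visit": visit})
            summary_rows[key][f"aecc_{name}_cortical"] = s.cortical_mean
            summary_rows[key][f"aecc_{name}_subcortical"] = s.subcortical_mean
            if cfg.get("write_matrices"):
                mat_dir.mkdir(exist_ok=True)
                pd.DataFrame(
                    cm.values, index=atlas.labels, columns=atlas.labels
                ).to_csv(
                    mat_dir / f"{subject}_{visit}_{name}.csv",
                    float_format="%.10g",
                )
    _float_csv(pd.DataFrame(profile_rows), outdir / "aecc_profiles.csv")
    summaries = pd.DataFrame(list(summary_rows.values()))
    _float_csv(summaries, outdir / "aecc_measures.csv")
    return summaries, matrices


def _model_rows(kind: str, result, extra: Mapping | None = None) -> list[dict]:
    rows = []
    for term, r in result.params.iterrows():
        rows.append(
            {
                "model": kind,
                "dependent": result.dependent,
                "term": term,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "alpha": result.alpha,
                "significant": r.p <= result.alpha,
                "n_obs": result.n_obs,
                "converged": result.converged,
                **(dict(extra) if extra else {}),
            }
        )
    return rows


def stage_stats(
    cfg: Mapping,
    table: pd.DataFrame,
    matrices: Mapping[str, list],
    seed: int,
    outdir: Path,
) -> pd.DataFrame:
    """Fit the full model battery and the permutation tests; write CSVs."""
    outdir.mkdir(parents=True, exist_ok=True)
    measure_cols = [
        m for m in SPECTRAL_MEASURES
        if f"{m}_cortical" in table.columns
    ]
    aecc_cols = sorted(
        {
            c[: -len("_cortical")]
            for c in table.columns
            if c.startswith("aecc_") and c.endswith("_cortical")
        }
    )
    rows: list[dict] = []
    failures: list[dict] = []

    def _try(kind, fn, *args, **kwargs):
        try:
            rows.extend(_model_rows(kind, fn(*args, **kwargs)))
        except Exception as exc:  # singular fits reported, not hidden
            failures.append(
                {"model": kind, "args": repr(args[1:]), "error": str(exc)}
            )

    for m in measure_cols + aecc_cols:
        for loc in ("cortical", "subcortical"):
            col = f"{m}_{loc}"
            _try("baseline_group", fit_baseline_group_model, table, col)
            _try("progression", fit_progression_model, table, col)
        _try("interaction", fit_interaction_model, table, m)
    for m in measure_cols:
        for loc in ("cortical", "subcortical"):
            for dep in ("CAMCOG", "UPDRS_III"):
                _try(
                    "clinical_association",
                    fit_clinical_association, table, dep, m, loc,
                )

    models = pd.DataFrame(rows)
    _float_csv(models, outdir / "model_results.csv")
    if failures:
        pd.DataFrame(failures).to_csv(outdir / "model_failures.csv", index=False)

    # connection-level permutation tests
    edge_frames = []
    bl = table[table["visit"] == "BL"]
    for name, mats in matrices.items():
        by_sv = {(s, v): cm for s, v, cm in mats}
        for label, ga, gb in (
            ("HC_vs_de_novo", "HC", "de_novo"),
            ("HC_vs_treated", "HC", "treated"),
        ):
            a = [by_sv[(s, "BL")] for s in bl[bl["group"] == ga]["subject"]
                 if (s, "BL") in by_sv]
            b = [by_sv[(s, "BL")] for s in bl[bl["group"] == gb]["subject"]
                 if (s, "BL") in by_sv]
            if len(a) < 2 or len(b) < 2:
                continue
            res = permutation_connection_test(
                a, b, n_permutations=cfg["n_permutations"], seed=seed,
            )
            frame = res.to_frame()
            frame.insert(0, "band", name)
            frame.insert(1, "contrast", label)
            edge_frames.append(frame)
        # paired BL vs FU1 in patients observed at both visits
        patients = table[table["group"].isin(["de_novo", "treated"])]
        subs = sorted(
            set(patients[patients["visit"] == "BL"]["subject"])
            & set(patients[patients["visit"] == "FU1"]["subject"])
        )
        subs = [s for s in subs if (s, "BL") in by_sv and (s, "FU1") in by_sv]
        if len(subs) >= 2:
            res = permutation_connection_test(
                [by_sv[(s, "BL")] for s in subs],
                [by_sv[(s, "FU1")] for s in subs],
                n_permutations=cfg["n_permutations"],
                paired=True, seed=seed,
                subjects_a=subs, subjects_b=subs,
            )
            frame = res.to_frame()
            frame.insert(0, "band", name)
            frame.insert(1, "contrast", "BL_vs_FU1_paired")
            edge_frames.append(frame)
    if edge_frames:
        _float_csv(
            pd.concat(edge_frames, ignore_index=True),
            outdir / "permutation_edges.csv",
        )
    return models


def run_all(
    config_path: str | Path | None, seed: int, outdir: str | Path
) -> pd.DataFrame:
    """simulate -> power -> connectivity -> stats, writing all reports."""
    cfg = load_config(config_path)
    outdir = Path(outdir)
    atlas = load_atlas()
    recordings = apply_downsampling(cfg, stage_simulate(cfg, seed, outdir))
    cohort = pd.read_csv(outdir / "cohort.csv")
    measures = stage_power(cfg, recordings, atlas, outdir)
    conn_summary, matrices = stage_connectivity(cfg, recordings, atlas, outdir)
    table = merge_measures(cohort, measures)
    if not conn_summary.empty:
        table = table.merge(conn_summary, on=["subject", "visit"], how="left")
    _float_csv(table, outdir / "cohort_with_measures.csv")
    return stage_stats(cfg, table, matrices, seed, outdir)
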
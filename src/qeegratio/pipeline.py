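"""End-to-end orchestration: generate/read -> preprocess -> spectra ->
ratios -> statistics, with a reproducibility manifest.

A single master seed drives every stochastic stage; two runs from the
same configuration are bit-identical (output files carry no timestamps
and the manifest records their SHA-256 checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .errors import InsufficientCleanDataError, PipelineError
from .io import read_eeg, read_metadata, write_metadata, write_recording
from .montage import DEFAULT_MONTAGE
from .preprocess import PreprocessConfig, preprocess_recording
from .ratios import compute_lobar_ratios, records_to_frame
from .recording import CONDITIONS
from .spectral import relative_band_power, welch_psd
from .stats import AnalysisConfig, analyze_cohort
from .synthetic import SimulationConfig, metadata_frame, simulate_metadata, \
    simulate_recording, SubjectRecord


@dataclass
class PipelineConfig:
    """Every protocol constant as a named key with its default value."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    welch_window_length: float = 2.0
    welch_overlap: float = 0.5
    log_base: float = 10.0
    per_channel_first: bool = False
    conditions: tuple[str, ...] = CONDITIONS

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        sim = d["simulation"]
        sim["planted_slopes"] = {
            f"{lobe}:{cond}": v
            for (lobe, cond), v in self.simulation.planted_slopes.items()
        }
        sim["osc_bands"] = {k: list(v) for k, v in sim["osc_bands"].items()}
        sim["montage"] = {"labels": list(self.simulation.montage.labels),
                          "lobe_map": dict(self.simulation.montage.lobe_map)}
        d["conditions"] = list(self.conditions)
        d["analysis"]["covariates"] = list(self.analysis.covariates)
        d["analysis"]["stratified_covariates"] = list(
            self.analysis.stratified_covariates)
        d["analysis"]["education_bounds"] = list(self.analysis.education_bounds)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        sim_kwargs = dict(data.pop("simulation", {}) or {})
        if "planted_slopes" in sim_kwargs and isinstance(
                sim_kwargs["planted_slopes"], dict):
            slopes = {}
            for key, v in sim_kwargs["planted_slopes"].items():
                if isinstance(key, str):
                    lobe, cond = key.split(":")
                    slopes[(lobe, cond)] = float(v)
                else:
                    slopes[tuple(key)] = float(v)
            sim_kwargs["planted_slopes"] = slopes
        if "osc_bands" in sim_kwargs:
            sim_kwargs["osc_bands"] = {k: tuple(v) for k, v in
                                       sim_kwargs["osc_bands"].items()}
        sim_kwargs.pop("montage", None)
        pre_kwargs = dict(data.pop("preprocess", {}) or {})
        ana_kwargs = dict(data.pop("analysis", {}) or {})
        for key in ("covariates", "stratified_covariates"):
            if key in ana_kwargs:
                ana_kwargs[key] = tuple(ana_kwargs[key])
        if "education_bounds" in ana_kwargs:
            ana_kwargs["education_bounds"] = tuple(ana_kwargs["education_bounds"])
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(simulation=SimulationConfig(**sim_kwargs),
                   preprocess=PreprocessConfig(**pre_kwargs),
                   analysis=AnalysisConfig(**ana_kwargs), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunManifest:
    """Config snapshot, version, seed, exclusions and output checksums."""

    config: dict[str, Any]
    version: str
    seed: int
    exclusions: list[dict[str, Any]]
    files: dict[str, str]
    n_subjects: int
    n_ratio_records: int

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def generate_cohort_files(config: PipelineConfig, out_dir: str | Path,
                          fmt: str = "delimited") -> list[Path]:
    """Write metadata.csv and one recording file per subject x condition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = simulate_metadata(config.simulation)
    written = [out / "metadata.csv"]
    write_metadata(subjects, written[0])
    ext = "edf" if fmt == "edf" else "csv"
    for subject in subjects:
        for cond in config.conditions:
            rec = simulate_recording(subject, cond, config.simulation)
            path = out / f"{subject.subject_id}_{cond}.{ext}"
            write_recording(rec, path, fmt)
            written.append(path)
    return written


def process_cohort(config: PipelineConfig, input_dir: str | Path | None = None,
                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                              list[dict[str, Any]]]:
    """Run preprocessing + spectral + ratio stages for the whole cohort.

    Returns (metadata, ratio records, rejection log, exclusions).  With
    ``input_dir`` set, recordings and metadata are read from files;
    otherwise they are simulated on the fly.  Exclusion is per
    subject x condition: a subject failing one condition still
    contributes the other.
    """
    sim = config.simulation
    if input_dir is None:
        subjects = simulate_metadata(sim)
        meta = metadata_frame(subjects)
    else:
        meta = read_metadata(Path(input_dir) / "metadata.csv")
        subjects = [
            SubjectRecord(
                subject_id=str(r.subject_id), age=float(r.age), sex=str(r.sex),
                education_years=int(r.education_years), kmmse=int(r.kmmse),
                oab=float(r.oab_ng_ml),
                amyloid_group="high" if float(r.oab_ng_ml) >= config.analysis.cutoff
                else "low",
            )
            for r in meta.itertuples()
        ]

    records = []
    log_rows = []
    exclusions = []
    for subject in subjects:
        for cond in config.conditions:
            sid = subject.subject_id
            try:
                if input_dir is None:
                    rec = simulate_recording(subject, cond, sim)
                else:
                    base = Path(input_dir) / f"{sid}_{cond}"
                    candidates = [base.with_suffix(s) for s in (".edf", ".csv")]
                    path = next((p for p in candidates if p.exists()), None)
                    if path is None:
                        raise FileNotFoundError(
                            f"no recording file for {sid} {cond} under {input_dir}")
                    rec = read_eeg(path, sampling_rate=sim.sampling_rate,
                                   montage=sim.montage, subject_id=sid,
                                   condition=cond,
                                   trial_length=sim.trial_length)
            except Exception as exc:   # noqa: BLE001 - abort with context
                raise PipelineError("load", sid, exc) from exc

            try:
                es = preprocess_recording(rec, config.preprocess)
            except InsufficientCleanDataError as exc:
                exclusions.append({"subject_id": sid, "condition": cond,
                                   "retained_seconds": exc.retained_seconds})
                log_rows.append({"subject_id": sid, "condition": cond,
                                 "epochs_total": int(
                                     rec.n_samples // (config.preprocess.epoch_length
                                                       * sim.sampling_rate)),
                                 "epochs_retained": int(
                                     exc.retained_seconds
                                     / config.preprocess.epoch_length),
                                 "excluded_flag": True})
                continue
            except Exception as exc:   # noqa: BLE001
                raise PipelineError("preprocess", sid, exc) from exc

            try:
                psd = welch_psd(es, config.welch_window_length,
                                config.welch_overlap)
                rbp = relative_band_power(psd)
                records.extend(compute_lobar_ratios(
                    rbp, sim.montage, sid, cond, config.log_base,
                    config.per_channel_first))
            except Exception as exc:   # noqa: BLE001
                raise PipelineError("spectral", sid, exc) from exc
            log_rows.append({"subject_id": sid, "condition": cond,
                             "epochs_total": es.n_epochs,
                             "epochs_retained": es.n_retained,
                             "excluded_flag": False})

    return meta, records_to_frame(records), pd.DataFrame(log_rows), exclusions


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 input_dir: str | Path | None = None) -> RunManifest:
    """Full pipeline run; emits report tables, logs and a manifest.

    On any stage error the partial outputs are removed and a
    :class:`PipelineError` naming the stage and subject is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        meta, ratio_df, log_df, exclusions = process_cohort(config, input_dir)
        try:
            tables = analyze_cohort(ratio_df, meta, config.analysis)
        except Exception as exc:   # noqa: BLE001
            raise PipelineError("stats", None, exc) from exc

        path = out / "metadata.csv"
        write_metadata(meta, path)
        written.append(path)
        path = out / "ratios.tsv"
        _write_tsv(ratio_df, path)
        written.append(path)
        path = out / "rejection_log.tsv"
        _write_tsv(log_df, path)
        written.append(path)
        for name, table in tables.items():
            path = out / f"{name}.tsv"
            _write_tsv(table, path)
            written.append(path)

        manifest = RunManifest(
            config=config.to_dict(),
            version=__version__,
            seed=config.simulation.seed,
            exclusions=exclusions,
            files={p.name: _sha256(p) for p in written},
            n_subjects=int(meta.shape[0]),
            n_ratio_records=int(ratio_df.shape[0]),
        )
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
        return manifest
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
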
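"""End-to-end pipeline: QC -> PLV -> classification -> statistics.

``run_pipeline`` takes a manifest of participant recordings (WAV audio
or precomputed envelope CSVs) plus the stimulus, screens each
recording, computes one PLV per participant, selects the mixture model
by AIC, classifies high/low synchronizers and runs the cohort
statistics — writing every intermediate table so a run is auditable
and, under fixed seeds, byte-reproducible.

``replicate_from_deposit`` skips the audio stages and applies the
mixture and statistics battery directly to a CSV of per-participant
PLVs (e.g. a deposited data export), optionally comparing summary
quantities against caller-supplied expected values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import AudioSignal, prefilter, quality_check, read_audio
from .mixture import MixtureFit, classify, select_k_by_aic
from .stats import run_group_comparisons
from .sync import (EnvelopeSeries, compute_plv, extract_envelope, phase_pair,
                   resample_and_band, spectral_profile)
from .synth import read_envelope_csv

logger = logging.getLogger("speechsync")

__all__ = ["RunConfig", "RunReport", "run_pipeline", "replicate_from_deposit"]


@dataclass
class RunConfig:
    """Settings for one pipeline run.

    The defaults are the protocol's analysis settings: envelopes at
    100 Hz, band-pass 3.5-5.5 Hz, 5 s windows with 2 s overlap, at
    most 140 EM iterations, 10,000 Monte-Carlo simulations.
    """

    input_manifest: str = ""
    stimulus_path: str = ""
    output_dir: str = "speechsync_out"
    band_hz: tuple[float, float] = (3.5, 5.5)
    window_s: float = 5.0
    overlap_s: float = 2.0
    resample_hz: float = 100.0
    silence_threshold: float = 0.05
    max_silence_s: float = 4.0
    gmm_max_iter: int = 140
    gmm_seed: int = 0
    gmm_n_init: int = 1
    mc_sims: int = 10_000
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.band_hz = tuple(self.band_hz)  # type: ignore[assignment]
        for name in ("window_s", "overlap_s", "resample_hz", "max_silence_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.window_s <= 0 or self.resample_hz <= 0:
            raise ValueError("window_s and resample_hz must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_hz"] = list(self.band_hz)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one pipeline run produced."""

    n_input: int
    n_excluded: int
    exclusion_reasons: dict
    plv_table: pd.DataFrame
    mixture: MixtureFit | None
    classification_counts: dict
    stats: dict | None
    provenance: dict = field(default_factory=dict)

    @property
    def n_analyzed(self) -> int:
        return self.n_input - self.n_excluded


def _load_envelope(path: Path, config: RunConfig, pid: str) -> EnvelopeSeries:
    """Raw (broadband) envelope of one input file at the analysis rate."""
    if path.suffix.lower() == ".wav":
        sig = read_audio(path, participant_id=pid)
        sig = prefilter(sig)
        env = extract_envelope(sig)
    else:
        env = read_envelope_csv(path, source_id=pid)
    return resample_and_band(env, target_hz=config.resample_hz, band=None)


def _qc_input(path: Path, config: RunConfig, pid: str):
    """QC report for one input; silence screening applies to envelopes too."""
    if path.suffix.lower() == ".wav":
        sig = read_audio(path, participant_id=pid)
        return quality_check(sig, silence_threshold=config.silence_threshold,
                             max_silence_s=config.max_silence_s)
    env = read_envelope_csv(path, source_id=pid)
    proxy = AudioSignal(env.values, env.sample_rate_hz, participant_id=pid)
    return quality_check(proxy, silence_threshold=config.silence_threshold,
                         max_silence_s=config.max_silence_s)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    The manifest CSV needs columns ``participant_id`` and ``path``
    (WAV or envelope CSV, relative paths resolved against the manifest
    location); covariate columns (``cohort, sex, age, edu_years,
    music_years, music_level, perceived_change``) are carried through
    to the statistics stage when present.  Multiple rows per
    participant are treated as repeated runs and their PLVs averaged.
    Per-participant failures are logged and recorded as exclusions;
    a config-level problem (missing manifest, empty manifest,
    unreadable stimulus) aborts.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest_path = Path(config.input_manifest)
    if not manifest_path.is_file():
        raise ValueError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    if not {"participant_id", "path"} <= set(manifest.columns):
        raise ValueError("manifest needs participant_id and path columns")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stim_path = Path(config.stimulus_path)
    if not stim_path.is_file():
        stim_path = manifest_path.parent / config.stimulus_path
    if not stim_path.is_file():
        raise ValueError(f"stimulus not found: {config.stimulus_path}")
    stim_env = _load_envelope(stim_path, config, "stimulus")
    stim_band = resample_and_band(stim_env, target_hz=config.resample_hz,
                                  band=config.band_hz)

    qc_rows, plv_rows, spectra = [], [], {}
    exclusions: dict[str, list[str]] = {}
    for pid, rows in manifest.groupby("participant_id", sort=False):
        run_plvs, run_windows = [], []
        reasons: list[str] = []
        for _, row in rows.iterrows():
            path = Path(row["path"])
            if not path.is_file():
                path = manifest_path.parent / row["path"]
            try:
                qc = _qc_input(path, config, str(pid))
                qc_rows.append({"participant_id": pid, "included": qc.included,
                                "reasons": ";".join(qc.reasons),
                                "longest_silence_s": qc.longest_silence_s,
                                "rms_level": qc.rms_level})
                if not qc.included:
                    reasons.extend(qc.reasons)
                    continue
                env = _load_envelope(path, config, str(pid))
                band = resample_and_band(env, target_hz=config.resample_hz,
                                         band=config.band_hz)
                pair = phase_pair(stim_band, band)
                res = compute_plv(pair, window_s=config.window_s,
                                  overlap_s=config.overlap_s)
                run_plvs.append(res.plv_mean)
                run_windows.append(res.plv_windows)
                spectra[pid] = spectral_profile(env)
            except Exception as exc:
                logger.warning("participant %s: %s", pid, exc)
                reasons.append(f"processing_error:{exc}")
        if run_plvs:
            rec = {"participant_id": pid, "plv": float(np.mean(run_plvs)),
                   "n_runs": len(run_plvs),
                   "n_windows": int(sum(len(w) for w in run_windows))}
            for col in ("cohort", "sex", "age", "edu_years", "music_years",
                        "music_level", "perceived_change"):
                if col in rows.columns:
                    rec[col] = rows.iloc[0][col]
            plv_rows.append(rec)
        else:
            exclusions[str(pid)] = sorted(set(reasons)) or ["no_usable_run"]

    n_input = manifest["participant_id"].nunique()
    plv_table = pd.DataFrame(plv_rows)
    pd.DataFrame(qc_rows).to_csv(out_dir / "qc_report.csv", index=False)

    fit = None
    counts: dict = {}
    stats_report = None
    if len(plv_table) >= 2:
        fit = select_k_by_aic(plv_table["plv"], max_iter=config.gmm_max_iter,
                              seed=config.gmm_seed, n_init=config.gmm_n_init)
        if fit.k == 2:
            cls = classify(fit, plv_table["plv"])
            plv_table["label"] = cls.labels
            plv_table["posterior_high"] = cls.posterior_high
            counts = {"n_high": cls.n_high, "n_low": cls.n_low,
                      "boundary_plv": cls.boundary_plv}
        (out_dir / "mixture_fit.json").write_text(json.dumps(fit.summary(), indent=2))
        if "label" in plv_table.columns:
            try:
                stats_report = run_group_comparisons(plv_table)
                (out_dir / "stats_report.json").write_text(
                    json.dumps(stats_report, indent=2, default=_jsonable))
            except ValueError as exc:
                logger.warning("statistics stage skipped: %s", exc)
    plv_table.to_csv(out_dir / "plv_table.csv", index=False)

    report = RunReport(
        n_input=int(n_input),
        n_excluded=len(exclusions),
        exclusion_reasons=exclusions,
        plv_table=plv_table,
        mixture=fit,
        classification_counts=counts,
        stats=stats_report,
        provenance={"config": config.to_dict(), "config_digest": config.digest(),
                    "version": __version__},
    )
    (out_dir / "run_report.json").write_text(json.dumps({
        "n_input": report.n_input, "n_excluded": report.n_excluded,
        "exclusion_reasons": report.exclusion_reasons,
        "classification": counts,
        "mixture": fit.summary() if fit else None,
        "provenance": report.provenance,
    }, indent=2, default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def replicate_from_deposit(plv_csv: str | Path, output_dir: str | Path | None = None,
                           gmm_max_iter: int = 140, gmm_seed: int = 0,
                           expected: dict | None = None,
                           tolerance: float = 0.01) -> dict:
    """Mixture + statistics battery on a deposited PLV table.

    ``plv_csv`` needs columns ``participant_id, cohort, plv``; rows
    with PLV outside [0, 1] are rejected with a reason.  Per cohort
    and combined: AIC model selection over 1-3 components, high/low
    classification when two components win, one-sample KS; with two
    cohorts, the between-cohort two-sample KS and Bayes factor.

    ``expected`` may map summary keys (e.g. ``"english.n_high"``,
    ``"combined.weight_high"``) to reference values; each is compared
    at ``tolerance`` (absolute) and a pass/fail table is included.
    """
    df = pd.read_csv(plv_csv)
    if not {"participant_id", "cohort", "plv"} <= set(df.columns):
        raise ValueError("deposit CSV needs participant_id, cohort, plv columns")
    bad = ~df["plv"].between(0.0, 1.0)
    rejected = df[bad]
    if len(rejected):
        logger.warning("rejected %d rows with PLV outside [0, 1]", len(rejected))
    df = df[~bad].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no valid PLV rows")

    sections: dict[str, pd.DataFrame] = {name: grp for name, grp in df.groupby("cohort")}
    if len(sections) > 1:
        sections["combined"] = df
    elif len(sections) == 1:
        logger.info("single-cohort deposit: between-cohort comparisons skipped")

    summary: dict = {"n_rejected_rows": int(bad.sum()), "sections": {}}
    for name, grp in sections.items():
        fit = select_k_by_aic(grp["plv"], max_iter=gmm_max_iter, seed=gmm_seed)
        sec = {"n": len(grp), "selected_k": fit.k, "fit": fit.summary()}
        if fit.k == 2:
            cls = classify(fit, grp["plv"])
            hi = int(np.argmax(fit.means))
            sec.update({
                "n_high": cls.n_high, "n_low": cls.n_low,
                "mean_high": float(fit.means[hi]), "mean_low": float(fit.means[1 - hi]),
                "sd_high": float(fit.sds[hi]), "sd_low": float(fit.sds[1 - hi]),
                "weight_high": float(fit.weights[hi]),
                "weight_low": float(fit.weights[1 - hi]),
                "boundary_plv": cls.boundary_plv,
            })
        from .stats import ks_one_sample
        ks = ks_one_sample(grp["plv"])
        sec["ks_d"] = ks.d_stat
        sec["ks_p"] = ks.p_value
        summary["sections"][name] = sec

    if len(sections) > 2:  # two cohorts + combined
        from .stats import bayes_factor_ttest, ks_two_sample
        names = [n for n in sections if n != "combined"]
        a = sections[names[0]]["plv"].to_numpy()
        b = sections[names[1]]["plv"].to_numpy()
        two = ks_two_sample(a, b)
        bf = bayes_factor_ttest(a, b)
        summary["between_cohorts"] = {
            "cohorts": names, "ks_d": two.d_stat, "ks_p": two.p_value,
            "bf01": bf.bf01, "posterior_mean": bf.posterior_mean,
            "credible_interval": list(bf.credible_interval),
        }

    if expected:
        comparisons = {}
        for key, ref in expected.items():
            sec_name, _, field_name = key.partition(".")
            node = summary.get("between_cohorts", {}) if sec_name == "between_cohorts" \
                else summary["sections"].get(sec_name, {})
            got = node.get(field_name)
            ok = got is not None and abs(float(got) - float(ref)) <= tolerance
            comparisons[key] = {"expected": ref, "observed": got, "pass": bool(ok)}
        summary["comparisons"] = comparisons

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "deposit_replication.json").write_text(
            json.dumps(summary, indent=2, default=_jsonable))
    return summary
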
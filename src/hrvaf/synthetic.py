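"""Seeded synthetic cohorts of annotated RR-interval recordings.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* **Sinus rhythm (SR)** — serially correlated, low-dispersion RR series:
  a mean-reverting AR(1) process plus a respiratory sinusoid (~0.25 Hz) and
  a very-low-frequency oscillation (~0.03 Hz).  The VLF term contributes to
  total variability (SDRR, CV) but changes little beat-to-beat, so SR can
  show sizable SDRR while successive differences stay small — which is what
  keeps pRR50 the cleanest single separator while CV/SDRR overlap with AF.
* **Atrial fibrillation (AF)** — weakly correlated, high-dispersion RR
  series: i.i.d. gamma durations with a controllable coefficient of
  variation and an optional small lag-1 moving-average blend.
* **Patient heterogeneity** — per-patient lognormal mean RR, and lognormal
  multiplicative spread on the SR noise level / VLF amplitude and the AF
  dispersion, so the two classes overlap in mean RR and partially in CV.
* **Artifacts** — per-beat probability of replacing an interval by a
  duration outside the physiological [240, 3000] ms band, labelled
  ``artifact``, for the preprocessing filters to remove.
* **Mixed-rhythm patients** — a fraction of patients get one labelled
  AF<->SR transition mid-recording, exercising the rhythm-purity filter.

Everything is driven by one integer seed; identical config + seed yields a
byte-identical cohort, with each patient on an independent counter-keyed
RNG stream so the result does not depend on generation order.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from ._errors import ConfigurationError
from .types import RRRecording

# generated (non-artifact) durations are kept strictly inside the
# physiological band so that injected artifacts are the only out-of-range
# intervals in a cohort
_GEN_RR_MIN = 260.0
_GEN_RR_MAX = 2980.0


@dataclass
class SRParams:
    """Sinus-rhythm model parameters (all durations/amplitudes in ms)."""

    mean_rr_mu: float = 900.0          # cohort mean of per-patient mean RR
    mean_rr_sigma: float = 90.0        # cohort SD of per-patient mean RR
    resp_amplitude: float = 25.0       # respiratory sinus arrhythmia amplitude
    resp_frequency: float = 0.25       # Hz
    ar1_coefficient: float = 0.8       # serial correlation of the fast noise
    noise_sd: float = 15.0             # innovation SD of the AR(1) noise
    noise_sd_spread: float = 0.5       # lognormal sigma of per-patient noise SD
    vlf_amplitude: float = 60.0        # very-low-frequency oscillation amplitude
    vlf_frequency: float = 0.03        # Hz
    vlf_amplitude_spread: float = 0.6  # lognormal sigma of per-patient VLF amp
    ectopy_rate: float = 0.05          # per-beat premature-beat probability
    ectopy_rate_spread: float = 0.8    # lognormal sigma of per-patient rate


@dataclass
class AFParams:
    """Atrial-fibrillation model parameters."""

    mean_rr_mu: float = 750.0
    mean_rr_sigma: float = 160.0
    dispersion_cv: float = 0.20        # target coefficient of variation
    dispersion_cv_spread: float = 0.6   # lognormal sigma of per-patient CV
    lag1_corr: float = 0.05            # target lag-1 autocorrelation, [0, 0.2]


@dataclass
class GeneratorConfig:
    n_patients_per_class: int = 40
    recording_duration: float = 300.0  # seconds
    seed: int = 0
    sr_params: SRParams = field(default_factory=SRParams)
    af_params: AFParams = field(default_factory=AFParams)
    artifact_rate: float = 0.01
    mixed_rhythm_fraction: float = 0.10

    def validate(self) -> None:
        if self.n_patients_per_class < 1:
            raise ConfigurationError("n_patients_per_class must be >= 1")
        if self.recording_duration <= 0:
            raise ConfigurationError("recording_duration must be positive")
        for name in ("artifact_rate", "mixed_rhythm_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        sr, af = self.sr_params, self.af_params
        if sr.mean_rr_mu <= 0 or af.mean_rr_mu <= 0:
            raise ConfigurationError("mean RR must be positive")
        if sr.mean_rr_sigma < 0 or af.mean_rr_sigma < 0:
            raise ConfigurationError("mean RR sigma must be non-negative")
        if not 0.0 <= sr.ar1_coefficient < 1.0:
            raise ConfigurationError("ar1_coefficient must lie in [0, 1)")
        if sr.noise_sd < 0 or sr.resp_amplitude < 0 or sr.vlf_amplitude < 0:
            raise ConfigurationError("SR amplitudes must be non-negative")
        if not 0.0 <= sr.ectopy_rate <= 1.0:
            raise ConfigurationError("ectopy_rate must lie in [0, 1]")
        if af.dispersion_cv < 0:
            raise ConfigurationError("dispersion_cv must be non-negative")
        if not 0.0 <= af.lag1_corr <= 0.2:
            raise ConfigurationError("lag1_corr must lie in [0, 0.2]")


def _patient_mean_rr(mu: float, sigma: float, rng: np.random.Generator) -> float:
    """Moment-matched lognormal draw of a per-patient mean RR (ms)."""
    if sigma <= 0:
        return float(mu)
    s2 = np.log1p((sigma / mu) ** 2)
    return float(rng.lognormal(np.log(mu) - s2 / 2.0, np.sqrt(s2)))


def _minimal_prefix(rr: np.ndarray, target_ms: float) -> np.ndarray:
    """Shortest prefix whose cumulative sum reaches ``target_ms``."""
    cs = np.cumsum(rr)
    if cs[-1] < target_ms:
        raise RuntimeError("generated series too short; internal margin bug")
    idx = int(np.searchsorted(cs, target_ms, side="left"))
    return rr[: idx + 1]


def implied_sr_lag1_corr(mean_rr_ms: float, noise_sd: float, ar1: float,
                         resp_amplitude: float, resp_frequency: float,
                         vlf_amplitude: float = 0.0,
                         vlf_frequency: float = 0.0) -> float:
    """Model-implied lag-1 autocorrelation of an SR series.

    Combines the AR(1) component with the sinusoids sampled at the nominal
    beat spacing (one mean RR).  Serves as the oracle for the empirical
    autocorrelation check.
    """
    dt = mean_rr_ms / 1000.0
    var_terms, cov_terms = [], []
    if noise_sd > 0 and ar1 < 1:
        v = noise_sd**2 / (1 - ar1**2)
        var_terms.append(v)
        cov_terms.append(ar1 * v)
    for amp, freq in ((resp_amplitude, resp_frequency), (vlf_amplitude, vlf_frequency)):
        if amp > 0:
            var_terms.append(amp**2 / 2)
            cov_terms.append(amp**2 / 2 * np.cos(2 * np.pi * freq * dt))
    if not var_terms:
        return 0.0
    return float(sum(cov_terms) / sum(var_terms))


def generate_sr_series(params: SRParams, duration: float,
                       rng: np.random.Generator, *,
                       patient_id: str = "SR000",
                       database_tag: str = "synthA") -> RRRecording:
    """Generate one sinus-rhythm recording covering ``duration`` seconds.

    The emitted series is the minimal prefix whose cumulative duration
    reaches the target.  All rhythm labels are ``SR``, all beats ``sinus``.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if not 0.0 <= params.ar1_coefficient < 1.0:
        raise ConfigurationError("ar1_coefficient must lie in [0, 1)")
    if params.noise_sd < 0 or params.resp_amplitude < 0 or params.vlf_amplitude < 0:
        raise ConfigurationError("SR amplitudes must be non-negative")

    mean = _patient_mean_rr(params.mean_rr_mu, params.mean_rr_sigma, rng)
    noise_sd = params.noise_sd * float(np.exp(rng.normal(0.0, params.noise_sd_spread))) \
        if params.noise_sd > 0 else 0.0
    vlf_amp = params.vlf_amplitude * float(np.exp(rng.normal(0.0, params.vlf_amplitude_spread))) \
        if params.vlf_amplitude > 0 else 0.0
    phase_resp = rng.uniform(0, 2 * np.pi)
    phase_vlf = rng.uniform(0, 2 * np.pi)

    target_ms = duration * 1000.0
    n = int(target_ms / mean * 1.4) + 64
    rho = params.ar1_coefficient
    if noise_sd > 0:
        e = rng.normal(0.0, noise_sd, n)
        x0 = rng.normal(0.0, noise_sd / np.sqrt(1 - rho**2))
        x, _ = lfilter([1.0], [1.0, -rho], e, zi=np.array([rho * x0]))
    else:
        x = np.zeros(n)
    t = np.arange(n) * (mean / 1000.0)  # nominal beat times, s
    rr = mean + x
    if params.resp_amplitude > 0:
        rr = rr + params.resp_amplitude * np.sin(2 * np.pi * params.resp_frequency * t + phase_resp)
    if vlf_amp > 0:
        rr = rr + vlf_amp * np.sin(2 * np.pi * params.vlf_frequency * t + phase_vlf)
    rr = np.clip(rr, min(_GEN_RR_MIN, mean), _GEN_RR_MAX)
    beats = np.full(n, "sinus", dtype=object)

    # premature (ectopic) beats: one shortened interval followed by a
    # compensatory pause.  They inflate SD1/RRdif-style magnitudes in SR
    # while moving the pRR50 count only a little -- the feature structure
    # real Holter SR shows.
    n_ectopic = 0
    if params.ectopy_rate > 0:
        rate = min(params.ectopy_rate
                   * float(np.exp(rng.normal(0.0, params.ectopy_rate_spread))), 0.15)
        idx = np.flatnonzero(rng.random(n) < rate)
        idx = idx[(idx > 0) & (idx < n - 1)]
        last = -2
        for i in idx:
            if i - last < 2:  # no back-to-back couplets
                continue
            last = int(i)
            frac = rng.uniform(0.25, 0.45)
            delta = rr[i] * frac
            rr[i] -= delta
            rr[i + 1] += delta * rng.uniform(0.8, 1.0)
            beats[i] = "supraventricular" if rng.random() < 0.7 else "ventricular"
            n_ectopic += 1
        rr = np.clip(rr, _GEN_RR_MIN, _GEN_RR_MAX)

    rr_cut = _minimal_prefix(rr, target_ms)
    k = len(rr_cut)
    return RRRecording(
        patient_id=patient_id, database_tag=database_tag, rr_ms=rr_cut,
        beat_label=beats[:k],
        rhythm_label=np.full(k, "SR", dtype=object),
        meta={"model": "SR", "mean_rr": mean, "noise_sd": noise_sd,
              "ar1": rho, "resp_amplitude": params.resp_amplitude,
              "resp_frequency": params.resp_frequency,
              "vlf_amplitude": vlf_amp, "vlf_frequency": params.vlf_frequency,
              "n_ectopic": n_ectopic},
    )


def _ma1_weight(lag1_corr: float) -> float:
    # lag-1 autocorrelation of the (1-w, w) blend is w(1-w)/(w^2+(1-w)^2);
    # closed-form inverse, smaller root
    if lag1_corr <= 0:
        return 0.0
    return 0.5 * (1.0 - np.sqrt(1.0 - 4.0 * lag1_corr / (1.0 + 2.0 * lag1_corr)))


def generate_af_series(params: AFParams, duration: float,
                       rng: np.random.Generator, *,
                       patient_id: str = "AF000",
                       database_tag: str = "synthA") -> RRRecording:
    """Generate one atrial-fibrillation recording covering ``duration`` s.

    Durations are i.i.d. gamma with the patient's coefficient of variation,
    optionally blended with the previous beat to reach a small lag-1
    autocorrelation.  All rhythm labels are ``AF``.
    """
    if duration <= 0:
        raise ConfigurationError("duration must be positive")
    if params.dispersion_cv < 0:
        raise ConfigurationError("dispersion_cv must be non-negative")
    if not 0.0 <= params.lag1_corr <= 0.2:
        raise ConfigurationError("lag1_corr must lie in [0, 0.2]")

    mean = _patient_mean_rr(params.mean_rr_mu, params.mean_rr_sigma, rng)
    cv = params.dispersion_cv * float(np.exp(rng.normal(0.0, params.dispersion_cv_spread))) \
        if params.dispersion_cv > 0 else 0.0
    cv = min(cv, 0.5)

    target_ms = duration * 1000.0
    n = int(target_ms / mean * 1.5) + 64
    if cv < 1e-9:
        rr = np.full(n, mean)
    else:
        shape = 1.0 / cv**2
        scale = mean * cv**2
        rr = rng.gamma(shape, scale, n)
        # rejection-resample the rare out-of-band draws so artifact injection
        # stays the only source of out-of-range durations
        bad = (rr < _GEN_RR_MIN) | (rr > _GEN_RR_MAX)
        while bad.any():
            rr[bad] = rng.gamma(shape, scale, int(bad.sum()))
            bad = (rr < _GEN_RR_MIN) | (rr > _GEN_RR_MAX)
        w = _ma1_weight(params.lag1_corr)
        if w > 0:
            d = rr - rr.mean()
            h = (1 - w) * d
            h[1:] += w * d[:-1]
            h /= np.sqrt(w**2 + (1 - w) ** 2)  # preserve the marginal SD
            rr = np.clip(rr.mean() + h, _GEN_RR_MIN, _GEN_RR_MAX)
    rr = _minimal_prefix(rr, target_ms)
    k = len(rr)
    return RRRecording(
        patient_id=patient_id, database_tag=database_tag, rr_ms=rr,
        beat_label=np.full(k, "sinus", dtype=object),
        rhythm_label=np.full(k, "AF", dtype=object),
        meta={"model": "AF", "mean_rr": mean, "cv": cv,
              "lag1_corr": params.lag1_corr},
    )


def inject_artifacts(recording: RRRecording, artifact_rate: float,
                     rng: np.random.Generator) -> RRRecording:
    """Replace a random subset of intervals by out-of-band artifact durations.

    Selected intervals get a duration outside [240, 3000] ms (half short,
    half long) and beat label ``artifact``; rhythm labels are untouched.
    With ``artifact_rate == 0`` the input is returned unchanged.
    """
    if not 0.0 <= artifact_rate <= 1.0:
        raise ConfigurationError("artifact_rate must lie in [0, 1]")
    if artifact_rate == 0.0:
        return recording
    n = len(recording)
    mask = rng.random(n) < artifact_rate
    k = int(mask.sum())
    rr = recording.rr_ms.copy()
    beats = recording.beat_label.copy()
    if k:
        short = rng.random(k) < 0.5
        vals = np.where(short, rng.uniform(60.0, 230.0, k), rng.uniform(3100.0, 5200.0, k))
        rr[mask] = vals
        beats[mask] = "artifact"
    meta = dict(recording.meta)
    meta["n_artifacts_injected"] = k
    return RRRecording(recording.patient_id, recording.database_tag, rr,
                       beats, recording.rhythm_label.copy(), meta)


def _patient_rng(seed: int, class_idx: int, patient_idx: int) -> np.random.Generator:
    # counter-keyed stream: reproducible independent of generation order
    return np.random.default_rng(np.random.SeedSequence([int(seed), class_idx, patient_idx]))


def generate_cohort(config: GeneratorConfig) -> tuple[list[RRRecording], pd.DataFrame]:
    """Generate the full two-class virtual cohort.

    Returns the recordings and a manifest (one row per patient with its
    nominal class, database tag and artifact bookkeeping).  Patients
    alternate between two database tags so that the per-database 2/3 split
    downstream is exercised.
    """
    config.validate()
    recordings: list[RRRecording] = []
    rows = []
    for class_idx, cls in enumerate(("AF", "SR")):
        for p in range(config.n_patients_per_class):
            rng = _patient_rng(config.seed, class_idx, p)
            pid = f"{cls}{p:03d}"
            db = "synthA" if p % 2 == 0 else "synthB"
            mixed = bool(rng.random() < config.mixed_rhythm_fraction)
            if mixed:
                # one labelled transition somewhere in the middle third
                frac = rng.uniform(0.4, 0.6)
                d1 = config.recording_duration * frac
                d2 = config.recording_duration - d1
                own = generate_sr_series if cls == "SR" else generate_af_series
                other = generate_af_series if cls == "SR" else generate_sr_series
                own_params = config.sr_params if cls == "SR" else config.af_params
                other_params = config.af_params if cls == "SR" else config.sr_params
                r1 = own(own_params, d1, rng, patient_id=pid, database_tag=db)
                r2 = other(other_params, d2, rng, patient_id=pid, database_tag=db)
                rec = RRRecording(
                    pid, db,
                    np.concatenate([r1.rr_ms, r2.rr_ms]),
                    np.concatenate([r1.beat_label, r2.beat_label]),
                    np.concatenate([r1.rhythm_label, r2.rhythm_label]),
                    meta={"model": "mixed", "primary_class": cls,
                          "transition_fraction": frac},
                )
            elif cls == "SR":
                rec = generate_sr_series(config.sr_params, config.recording_duration,
                                         rng, patient_id=pid, database_tag=db)
            else:
                rec = generate_af_series(config.af_params, config.recording_duration,
                                         rng, patient_id=pid, database_tag=db)
            rec = inject_artifacts(rec, config.artifact_rate, rng)
            recordings.append(rec)
            rows.append({
                "patient_id": pid, "database_tag": db, "true_class": cls,
                "mixed_rhythm": mixed, "n_intervals": len(rec),
                "duration_ms": rec.duration_ms,
                "n_artifacts": rec.meta.get("n_artifacts_injected", 0),
            })
    return recordings, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hand-checkable fixtures for the preprocessing filters


@dataclass
class FilterFixture:
    """A hand-constructed recording with a documented expected outcome."""

    name: str
    recording: RRRecording
    expected_segments: int
    note: str


def _fixture(name: str, rr, rhythm, beats=None) -> RRRecording:
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    rhythm = np.asarray(rhythm, dtype=object) if not isinstance(rhythm, str) \
        else np.full(n, rhythm, dtype=object)
    if beats is None:
        beats = np.where((rr < 240) | (rr > 3000), "artifact", "sinus").astype(object)
    return RRRecording(f"FX-{name}", "fixture", rr, beats, rhythm)


def make_filter_fixtures() -> list[FilterFixture]:
    """Hand-constructed recordings exercising each segment-filter branch.

    Every fixture is built so its windows sum to exact multiples of 60 000 ms,
    making the expected surviving-segment count checkable by hand.
    """
    out = []

    # 150 x 800 ms = 120 000 ms: two clean pure-SR windows of 75 beats.
    out.append(FilterFixture(
        "pure_sr", _fixture("pure_sr", [800.0] * 150, "SR"), 2,
        "two complete 60 s windows, 75 retained intervals each, nothing removed"))

    # 50 alternating (520, 680) pairs = 60 000 ms: one clean pure-AF window.
    out.append(FilterFixture(
        "pure_af", _fixture("pure_af", [520.0, 680.0] * 50, "AF"), 1,
        "one complete window; every |successive difference| = 160 ms"))

    # One window containing both rhythms: excluded by the purity rule.
    mixed_rhythm = ["SR"] * 37 + ["AF"] * 38
    out.append(FilterFixture(
        "mixed_rhythm", _fixture("mixed_rhythm", [800.0] * 75, mixed_rhythm), 0,
        "window mixes AF and SR labels -> excluded"))

    # One window labelled 'other': also excluded.
    out.append(FilterFixture(
        "other_rhythm", _fixture("other_rhythm", [800.0] * 75, "other"), 0,
        "window contains a non-AF/SR rhythm -> excluded"))

    # Artifact-light: removed durations sum to 3000 ms < 6000 ms -> kept.
    light = [800.0] * 30 + [200.0] * 15 + [800.0] * 39 + [900.0] * 2
    assert sum(light) == 60000.0
    out.append(FilterFixture(
        "artifact_light", _fixture("artifact_light", light, "SR"), 1,
        "15 short artifacts removed, 3000 ms total < 6000 ms -> window kept "
        "with 71 retained intervals"))

    # Artifact-heavy: removed durations sum to 6500 ms >= 6000 ms -> dropped.
    heavy = [800.0] * 30 + [3500.0] + [200.0] * 15 + [800.0] * 36 + [700.0]
    assert sum(heavy) == 60000.0
    out.append(FilterFixture(
        "artifact_heavy", _fixture("artifact_heavy", heavy, "SR"), 0,
        "removed durations total 6500 ms >= 10% of the 60 s window -> discarded"))

    return out


# ---------------------------------------------------------------------------
# delimited-text persistence


def write_cohort(recordings: list[RRRecording], manifest: pd.DataFrame,
                 out_dir: str | Path, config: GeneratorConfig | None = None) -> Path:
    """Write a cohort as delimited text: one row per interval plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "patient_id": rec.patient_id, "database_tag": rec.database_tag,
            "rr_ms": rec.rr_ms, "beat_label": rec.beat_label,
            "rhythm_label": rec.rhythm_label,
        }))
    pd.concat(frames, ignore_index=True).to_csv(out / "intervals.csv", index=False)
    payload = {"patients": manifest.to_dict(orient="records")}
    if config is not None:
        payload["generator"] = dataclasses.asdict(config)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return out


def read_cohort(in_dir: str | Path) -> tuple[list[RRRecording], pd.DataFrame]:
    """Read a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    df = pd.read_csv(in_dir / "intervals.csv")
    with open(in_dir / "manifest.yaml") as fh:
        payload = yaml.safe_load(fh)
    manifest = pd.DataFrame(payload["patients"])
    recordings = []
    for (pid, db), grp in df.groupby(["patient_id", "database_tag"], sort=False):
        recordings.append(RRRecording(
            str(pid), str(db), grp["rr_ms"].to_numpy(),
            grp["beat_label"].to_numpy(dtype=object),
            grp["rhythm_label"].to_numpy(dtype=object)))
    return recordings, manifest


__all__ = [
    "SRParams", "AFParams", "GeneratorConfig", "FilterFixture",
    "generate_sr_series", "generate_af_series", "inject_artifacts",
    "generate_cohort", "make_filter_fixtures", "implied_sr_lag1_corr",
    "write_cohort", "read_cohort", "replace",
]
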
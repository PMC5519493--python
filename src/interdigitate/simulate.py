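"""Synthetic multi-session surface fMRI with planted distributed networks.

Signal model per vertex v and frame t::

    x_v(t) = sum_k w_vk * s_k(t) + g(t) + eps_v(t)

where ``s_k`` are independent unit-variance latent network time courses
with all spectral power below ``latent_lowpass_cutoff`` (spontaneous
activity is low frequency), ``w_vk`` equals ``network_loading`` on the
support of network k and 0 elsewhere (optionally attenuated inside a
susceptibility-dropout zone), ``g`` is a shared global signal and
``eps_v`` is white vertex noise.  A study is S subjects x R sessions;
odd-numbered sessions form the discovery half, even-numbered the
replication half, mirroring the within-individual split-half design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mesh import SurfaceMesh, build_icosphere
from .templates import NetworkTemplate, plant_networks

MIN_FRAMES = 64  # spectral floor: fALFF needs usable frequency resolution


@dataclass
class GeneratorParams:
    """Study-generator configuration.

    Defaults emulate the acquisition design this analysis was built for:
    4 subjects, 24 sessions each at TR = 1 s with 422-frame runs
    (7 m 2 s), latent network activity below 0.08 Hz, and two
    interdigitated networks planted across six zones (one lateral-PFC
    analogue used for seed search plus five distributed test zones).
    """

    subdivision_level: int = 4
    n_subjects: int = 4
    n_sessions: int = 24
    frames_per_run: int = 422
    tr_seconds: float = 1.0
    n_networks: int = 2
    n_zones: int = 6
    parcel_radius: int = 2
    zone_radius: int | None = None
    network_loading: float = 1.0
    vertex_noise_sd: float = 1.0
    global_signal_sd: float = 0.5
    baseline: float = 200.0   # mean signal level; sets the tSNR scale
    latent_lowpass_cutoff: float = 0.08
    jitter_steps: int = 2
    dropout_zone: int | None = None
    dropout_attenuation: float = 1.0   # multiplies signal in dropout zone; 1 = none
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.vertex_noise_sd < 0 or self.global_signal_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.dropout_attenuation <= 1.0):
            raise ValueError("dropout_attenuation must lie in [0, 1]")
        nyquist = 0.5 / self.tr_seconds
        if not (0.0 < self.latent_lowpass_cutoff < nyquist):
            raise ValueError("latent_lowpass_cutoff must lie in (0, Nyquist)")
        if self.network_loading < 0:
            raise ValueError("network_loading must be >= 0")


@dataclass
class SessionTimeseries:
    """One run of vertex x time signal plus its nuisance regressor table."""

    data: np.ndarray               # (V, T) float64
    tr_seconds: float
    nuisance: pd.DataFrame         # (T, n_regressors)
    run_id: int
    subject_id: int
    rng_seed: int | None = None

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def copy_with(self, **kw) -> "SessionTimeseries":
        return replace(self, **kw)

    def validate(self) -> None:
        if np.isnan(self.data).any():
            raise ValueError("time series contains missing values")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if self.n_frames < 2 * (2 * self.nuisance.shape[1]):
            raise ValueError("run too short for its nuisance design")


@dataclass
class StudyDataset:
    """All sessions of a simulated study plus ground truth."""

    mesh: SurfaceMesh
    params: GeneratorParams
    templates: dict[int, NetworkTemplate]
    sessions: dict[tuple[int, int], SessionTimeseries] = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[int]:
        return sorted(self.templates)

    def run_ids(self, subject: int) -> list[int]:
        return sorted(r for (s, r) in self.sessions if s == subject)

    @staticmethod
    def dataset_label(run_id: int) -> str:
        """Odd-numbered sessions are discovery, even replication."""
        return "discovery" if run_id % 2 == 1 else "replication"

    def discovery(self, subject: int) -> list[SessionTimeseries]:
        return [self.sessions[(subject, r)] for r in self.run_ids(subject) if r % 2 == 1]

    def replication(self, subject: int) -> list[SessionTimeseries]:
        return [self.sessions[(subject, r)] for r in self.run_ids(subject) if r % 2 == 0]

    def map_sessions(self, fn) -> "StudyDataset":
        """Apply ``fn(SessionTimeseries) -> SessionTimeseries`` to every run."""
        out = StudyDataset(mesh=self.mesh, params=self.params, templates=self.templates)
        out.sessions = {k: fn(ts) for k, ts in sorted(self.sessions.items())}
        return out


def lowpass_latents(rng: np.random.Generator, n: int, t: int,
                    cutoff_hz: float, tr: float) -> np.ndarray:
    """Independent unit-variance latents with zero power above the cutoff.

    White noise is brick-wall filtered in the frequency domain (bins with
    f > cutoff, and DC, are zeroed) and rescaled to unit variance, so the
    spectral constraint holds exactly.
    """
    x = rng.standard_normal((n, t))
    spec = np.fft.rfft(x, axis=1)
    f = np.fft.rfftfreq(t, d=tr)
    spec[:, (f > cutoff_hz) | (f == 0.0)] = 0.0
    y = np.fft.irfft(spec, n=t, axis=1)
    sd = y.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def simulate_session(
    template: NetworkTemplate,
    params: GeneratorParams,
    seed: int,
    run_id: int = 1,
    subject_id: int = 0,
) -> SessionTimeseries:
    """Simulate one run under the shared-latent signal model.

    Reproducible for a fixed ``seed``; each network's latent time course
    is generated independently; dropout attenuation multiplies the
    planted signal only (noise and global signal are unaffected).
    """
    t = params.frames_per_run
    if t < MIN_FRAMES:
        raise ValueError(
            f"frames_per_run={t} < {MIN_FRAMES}: insufficient spectrum for fALFF"
        )
    v = len(template.assignment)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E55]))

    latents = lowpass_latents(rng, template.n_networks, t,
                              params.latent_lowpass_cutoff, params.tr_seconds)
    weights = np.zeros((v, template.n_networks))
    for k in range(1, template.n_networks + 1):
        weights[template.assignment == k, k - 1] = params.network_loading
    if params.dropout_zone is not None:
        in_zone = template.zone_label == params.dropout_zone
        weights[in_zone] *= params.dropout_attenuation

    data = weights @ latents
    g = rng.standard_normal(t) * params.global_signal_sd
    data += g[None, :] + params.baseline
    if params.vertex_noise_sd > 0:
        data += rng.standard_normal((v, t)) * params.vertex_noise_sd

    motion = lowpass_latents(rng, 6, t, 0.1, params.tr_seconds) * 0.1
    nuisance = pd.DataFrame(
        {"global": g, **{f"motion_{i + 1}": motion[i] for i in range(6)}}
    )
    return SessionTimeseries(data=data, tr_seconds=params.tr_seconds,
                             nuisance=nuisance, run_id=run_id,
                             subject_id=subject_id, rng_seed=int(seed))


def subject_template(mesh: SurfaceMesh, params: GeneratorParams,
                     subject_id: int) -> NetworkTemplate:
    """Per-subject jittered template (shared when jitter_steps = 0)."""
    seed = 0 if params.jitter_steps == 0 else int(
        np.random.SeedSequence([params.master_seed, 0x7E3, subject_id]).generate_state(1)[0]
        % (2**31)
    )
    return plant_networks(
        mesh, n_networks=params.n_networks, n_zones=params.n_zones,
        parcel_radius=params.parcel_radius, jitter_steps=params.jitter_steps,
        subject_seed=seed, zone_radius=params.zone_radius,
    )


def session_seed(params: GeneratorParams, subject_id: int, run_id: int) -> int:
    ss = np.random.SeedSequence([params.master_seed, 0x5E55, subject_id, run_id])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_study(params: GeneratorParams, mesh: SurfaceMesh | None = None,
                   subjects: list[int] | None = None) -> StudyDataset:
    """Simulate the full S-subject x R-session study container.

    All randomness derives deterministically from ``params.master_seed``:
    the same parameters give a bit-identical study.  ``subjects`` allows
    generating a subset (e.g. one subject at a time) without changing
    any per-subject seed.
    """
    if mesh is None:
        mesh = build_icosphere(params.subdivision_level)
    if subjects is None:
        subjects = list(range(params.n_subjects))
    templates = {s: subject_template(mesh, params, s) for s in subjects}
    study = StudyDataset(mesh=mesh, params=params, templates=templates)
    for s in subjects:
        for r in range(1, params.n_sessions + 1):
            study.sessions[(s, r)] = simulate_session(
                templates[s], params, seed=session_seed(params, s, r),
                run_id=r, subject_id=s,
            )
    return study
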
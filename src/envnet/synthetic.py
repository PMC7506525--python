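"""Synthetic resting-state cohorts with controlled envelope coupling.

Generates band-limited node timecourses whose slow amplitude envelopes
carry a prescribed correlation structure, with optional zero-lag linear
leakage between nodes, group-specific envelope-correlation reductions at
designated "affected" edges, and demographic covariates — everything the
downstream connectivity, group-statistics, graph and classification
stages need, with known ground truth.

The envelope model is a log-normal one: correlated Gaussian processes are
low-pass filtered to the envelope bandwidth, standardized, and
exponentiated, giving strictly positive slow envelopes whose *latent*
correlation equals the requested target.  Each node's signal is a
band-limited white-noise carrier multiplied by its envelope.  Measured
envelope correlations attenuate relative to the latent target (carrier
amplitude noise, filtering, 1 Hz averaging), so the generator guarantees
ordering of coupling strengths rather than exact correlation values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .connectivity import (
    BandSpec,
    CANONICAL_BANDS,
    NodeTimecourses,
    edge_pairs,
    n_edges,
)

__all__ = [
    "CovariateParams",
    "SimulationConfig",
    "SubjectRecord",
    "make_effect_edges",
    "build_target_matrices",
    "generate_band_signal",
    "apply_leakage",
    "generate_cohort",
]


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateParams:
    """Per-group demographic distributions.

    Ages are normal (truncated at 18), gender is balanced at
    ``gender_prop`` (coded 1 = female), and intracranial volume (ICV) is
    normal in units of 1-mm isotropic voxels.  Defaults mirror a cohort
    of adult carriers of neurodevelopmental copy number variants and
    age/gender-matched controls, with a small case ICV deficit so the
    covariate-regression path is exercised.
    """

    age_mean: float
    age_sd: float
    gender_prop: float = 0.5
    icv_mean: float = 1.5e6
    icv_sd: float = 1.2e5


DEFAULT_COVARIATES: dict[str, CovariateParams] = {
    "case": CovariateParams(age_mean=38.5, age_sd=12.5, icv_mean=1.45e6),
    "control": CovariateParams(age_mean=33.3, age_sd=9.6, icv_mean=1.50e6),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    ``baseline_corr`` is the mean target envelope correlation of
    unaffected edges; ``baseline_spread`` is the fractional spread of a
    fixed per-edge baseline profile shared by every subject (real
    connectomes have a stable strong-edge backbone, which is what makes
    group-level rank maps meaningful; 0 gives a flat, exchangeable
    baseline).  ``effect_delta`` is the fractional reduction of the
    target envelope correlation at affected edges in the case group
    (0 = no group effect).  ``leakage_lambda`` scales the zero-lag
    linear mixing applied to every subject's signals.  ``env_log_sigma``
    sets the log-amplitude SD of the log-normal envelopes (modulation
    depth).
    """

    n_per_group: int = 42
    n_nodes: int = 90
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    sampling_rate: float = 600.0
    duration: float = 250.0
    baseline_corr: float = 0.3
    baseline_spread: float = 0.5
    affected_edge_count: int = 30
    effect_delta: float = 0.5
    leakage_lambda: float = 0.1
    envelope_bandwidth: float = 0.5
    env_log_sigma: float = 0.5
    covariate_params: dict[str, CovariateParams] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if not (0 <= self.baseline_corr < 1):
            raise ValueError("baseline_corr must lie in [0, 1)")
        if not (0 <= self.baseline_spread <= 1):
            raise ValueError("baseline_spread must lie in [0, 1]")
        if not (0 <= self.effect_delta <= 1):
            raise ValueError("effect_delta must lie in [0, 1]")
        if self.leakage_lambda < 0:
            raise ValueError("leakage_lambda must be >= 0")
        if self.affected_edge_count > n_edges(self.n_nodes):
            raise ValueError(
                f"affected_edge_count {self.affected_edge_count} exceeds "
                f"the {n_edges(self.n_nodes)} available edges"
            )
        for g in ("case", "control"):
            if g not in self.covariate_params:
                raise ValueError(f"covariate_params missing group {g!r}")


@dataclass
class SubjectRecord:
    """One generated subject: identity, covariates, per-band signals."""

    subject_id: str
    group: str  # "case" or "control"
    age: float
    gender: int  # 1 = female
    icv: float
    timecourses: dict[str, NodeTimecourses]  # band name -> signals


# --------------------------------------------------------------------------
# Ground-truth effect edges and target correlation matrices
# --------------------------------------------------------------------------

def make_effect_edges(
    n_nodes: int, affected_edge_count: int, seed: int
) -> np.ndarray:
    """Uniformly sample distinct upper-triangle edge indices.

    Returns a sorted array of edge indices in the fixed 0-based i<j
    lexicographic convention; deterministic given ``seed``.
    """
    total = n_edges(n_nodes)
    if affected_edge_count > total:
        raise ValueError(
            f"cannot pick {affected_edge_count} of {total} edges"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=affected_edge_count, replace=False)
    return np.sort(idx)


def _repair_psd(m: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues to 0 and rescale to unit diagonal."""
    lam, v = np.linalg.eigh((m + m.T) / 2.0)
    if lam[0] >= 0:
        return m
    lam = np.clip(lam, 0.0, None)
    rep = (v * lam) @ v.T
    d = np.sqrt(np.diag(rep))
    d[d == 0] = 1.0
    rep = rep / np.outer(d, d)
    np.fill_diagonal(rep, 1.0)
    return rep


def build_target_matrices(
    config: SimulationConfig,
    affected_edges: np.ndarray,
    profile_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(control_target, case_target) envelope-correlation matrices.

    The control target carries a fixed per-edge baseline profile,
    ``baseline_corr * (1 + baseline_spread * u_e)`` with u_e uniform on
    [-1, 1] drawn once per cohort — the stable connectome backbone that
    every subject shares.  The case target reduces the affected edges
    by ``effect_delta`` (fractional).  Both are PSD-repaired by
    eigenvalue clipping and rescaled to unit diagonal.
    """
    n = config.n_nodes
    i, j = edge_pairs(n)
    rng = np.random.default_rng(profile_seed)
    u = rng.uniform(-1.0, 1.0, i.size)
    edge_base = config.baseline_corr * (1.0 + config.baseline_spread * u)
    base = np.eye(n)
    base[i, j] = base[j, i] = edge_base
    case = base.copy()
    ai, aj = i[affected_edges], j[affected_edges]
    case[ai, aj] = case[aj, ai] = (
        edge_base[affected_edges] * (1.0 - config.effect_delta)
    )
    return _repair_psd(base), _repair_psd(case)


# --------------------------------------------------------------------------
# Signal generation
# --------------------------------------------------------------------------

def _correlated_lowpass(
    n_times: int,
    target: np.ndarray,
    bandwidth: float,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standardized low-pass Gaussian processes with given correlation.

    The latent process is synthesized at a coarse rate (20x the envelope
    bandwidth) where the low-pass Butterworth is numerically
    well-conditioned, then linearly interpolated to the signal rate;
    filtering directly at ``fs`` would put the normalized cutoff so low
    that the filter becomes unstable.
    """
    lam, v = np.linalg.eigh((target + target.T) / 2.0)
    lam = np.clip(lam, 0.0, None)
    factor = v * np.sqrt(lam)  # factor @ factor.T == target (after clip)
    fs_env = min(20.0 * bandwidth, fs)
    n_coarse = max(int(np.ceil(n_times * fs_env / fs)) + 2, 16)
    g = rng.standard_normal((n_coarse, target.shape[0])) @ factor.T
    sos = sps.butter(4, bandwidth, btype="lowpass", fs=fs_env,
                     output="sos")
    padlen = min(n_coarse - 1, int(6 * fs_env / bandwidth))
    g = sps.sosfiltfilt(sos, g, axis=0, padlen=padlen)
    g -= g.mean(axis=0)
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    g /= sd
    t_fine = np.arange(n_times) / fs
    t_coarse = np.arange(n_coarse) / fs_env
    out = np.empty((n_times, target.shape[0]))
    for k in range(target.shape[0]):
        out[:, k] = np.interp(t_fine, t_coarse, g[:, k])
    return out


def generate_band_signal(
    n_nodes: int,
    duration: float,
    fs: float,
    band: BandSpec,
    target_env_corr: np.ndarray,
    envelope_bandwidth: float = 0.5,
    seed: int | np.random.Generator = 0,
    env_log_sigma: float = 0.5,
) -> np.ndarray:
    """One band-limited signal matrix with prescribed envelope coupling.

    Each node's signal is a white-noise carrier band-passed to ``band``,
    amplitude-modulated by a strictly positive log-normal envelope; the
    latent (log-envelope) correlation matrix equals ``target_env_corr``
    after PSD repair.  Columns are zero-mean.
    """
    target = np.asarray(target_env_corr, dtype=float)
    if target.ndim != 2 or target.shape[0] != target.shape[1]:
        raise ValueError("target envelope correlation must be square")
    if target.shape[0] != n_nodes:
        raise ValueError(
            f"target is {target.shape[0]}x{target.shape[0]} but "
            f"n_nodes={n_nodes}"
        )
    if not np.allclose(target, target.T, atol=1e-10):
        raise ValueError("target envelope correlation must be symmetric")
    if fs <= 2 * band.f_hi:
        raise ValueError(
            f"sampling rate {fs} Hz cannot represent band "
            f"{band.name!r} (upper edge {band.f_hi} Hz)"
        )
    rng = np.random.default_rng(seed)
    n_times = int(round(duration * fs))
    target = _repair_psd(target)

    g = _correlated_lowpass(n_times, target, envelope_bandwidth, fs, rng)
    envelope = np.exp(env_log_sigma * g)

    sos = sps.butter(4, [band.f_lo, band.f_hi], btype="bandpass",
                     fs=fs, output="sos")
    padlen = min(n_times - 1, int(6 * fs / band.f_lo))
    carrier = sps.sosfiltfilt(
        sos, rng.standard_normal((n_times, n_nodes)), axis=0,
        padlen=padlen,
    )
    x = carrier * envelope
    return x - x.mean(axis=0)


def apply_leakage(
    signals: np.ndarray,
    leakage_lambda: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Mix node signals with a fixed symmetric zero-lag leakage matrix.

    Output = input @ (I + lambda * R), with R a random symmetric
    zero-diagonal matrix with unit-scale entries drawn from ``seed``;
    each output column is rescaled to retain its input variance, so
    leakage changes correlations, not signal power.
    """
    if leakage_lambda < 0:
        raise ValueError("leakage_lambda must be >= 0")
    x = np.asarray(signals, dtype=float)
    if leakage_lambda == 0:
        return x.copy()
    n = x.shape[1]
    rng = np.random.default_rng(seed)
    b = rng.standard_normal((n, n))
    r = (b + b.T) / np.sqrt(2.0)
    np.fill_diagonal(r, 0.0)
    y = x @ (np.eye(n) + leakage_lambda * r)
    sd_in = x.std(axis=0)
    sd_out = y.std(axis=0)
    sd_out[sd_out == 0] = 1.0
    return y * (sd_in / sd_out)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _draw_covariates(
    group: str, n: int, params: CovariateParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 18, None)
    n_f = int(round(params.gender_prop * n))
    gender = np.zeros(n, dtype=int)
    gender[:n_f] = 1
    rng.shuffle(gender)
    icv = rng.normal(params.icv_mean, params.icv_sd, n)
    return age, gender, icv


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectRecord], list[dict], np.ndarray]:
    """Generate a full two-group cohort of band-limited timecourses.

    Returns ``(subjects, manifest, affected_edges)``: the subject
    records with per-band signals, a JSON-serializable manifest (one
    entry per subject), and the ground-truth affected edge indices.

    Case subjects' target envelope correlations are reduced by
    ``effect_delta`` at the affected edges; controls use the baseline
    target.  Each subject gets an independent signal realization per
    band and a subject-specific leakage mixing matrix (emulating
    subject-specific source geometry).  Bit-identical reproducible from
    ``config`` (all randomness descends from ``config.seed``).
    """
    ss = np.random.SeedSequence(config.seed)
    edge_seed_ss, cov_ss, subj_root, profile_ss = ss.spawn(4)
    affected = make_effect_edges(
        config.n_nodes,
        config.affected_edge_count,
        seed=edge_seed_ss.generate_state(1)[0] % (2**31),
    )
    control_t, case_t = build_target_matrices(
        config, affected,
        profile_seed=int(profile_ss.generate_state(1)[0] % (2**31)),
    )

    cov_rng = np.random.default_rng(cov_ss)
    covs = {
        g: _draw_covariates(
            g, config.n_per_group, config.covariate_params[g], cov_rng
        )
        for g in ("case", "control")
    }

    subjects: list[SubjectRecord] = []
    manifest: list[dict] = []
    subj_seeds = subj_root.spawn(2 * config.n_per_group)
    k = 0
    for group, target in (("case", case_t), ("control", control_t)):
        age, gender, icv = covs[group]
        for s in range(config.n_per_group):
            sid = f"{group}_{s:03d}"
            srng = np.random.default_rng(subj_seeds[k])
            k += 1
            tcs: dict[str, NodeTimecourses] = {}
            # one mixing matrix per subject, shared across bands
            # (leakage reflects subject geometry, not frequency)
            leak_seed = int(srng.integers(2**31))
            for band in config.bands:
                x = generate_band_signal(
                    config.n_nodes,
                    config.duration,
                    config.sampling_rate,
                    band,
                    target,
                    envelope_bandwidth=config.envelope_bandwidth,
                    seed=srng,
                    env_log_sigma=config.env_log_sigma,
                )
                if config.leakage_lambda > 0:
                    x = apply_leakage(x, config.leakage_lambda,
                                      seed=leak_seed)
                tcs[band.name] = NodeTimecourses(
                    sid, config.sampling_rate, x, band=band
                )
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    age=float(age[s]),
                    gender=int(gender[s]),
                    icv=float(icv[s]),
                    timecourses=tcs,
                )
            )
            manifest.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": float(age[s]),
                    "gender": int(gender[s]),
                    "icv": float(icv[s]),
                    "bands": [b.name for b in config.bands],
                }
            )
    return subjects, manifest, affected
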
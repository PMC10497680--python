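"""Randomized configuration generation for interaction-site dimers.

For each accepted configuration: draw the five angles uniformly over the
sites' allowed interval unions, draw the vdW separation r from a biased
radial density (uniform on [r_min, r_switch], decreasing linearly to zero
at r_max), solve the translation for the matching r_PL, perturb every atom
by <=0.1 Å, evaluate the interaction energy, and accept when the total is
below threshold (20 kcal/mol, or 200 for like-charged pairs).  After the
k-th consecutive rejection the radial upper bound shrinks to
r_rejected + k*0.1 Å (r_rejected fixed at the chain's first rejected draw)
and resets to r_max upon acceptance, so the low-r region stays represented
without looping forever on impossible separations.

Randomness is a counter-based Philox stream; the per-site-dimer sub-stream
is keyed by (seed, site-dimer ordinal) so batches are reproducible and
order-insensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .energy import RejectionPolicy, accept_energy
from .geometry import InfeasibleSeparationError, InternalCoords
from .pairing import SiteDimer


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class RadialSpec:
    """Bounds of the biased radial density (Å): r_min <= r_switch <= r_max."""

    r_min: float
    r_switch: float
    r_max: float

    def __post_init__(self):
        if not (self.r_min <= self.r_switch <= self.r_max):
            raise SamplingError(
                f"need r_min <= r_switch <= r_max, got "
                f"({self.r_min}, {self.r_switch}, {self.r_max})"
            )
        if not all(map(math.isfinite, (self.r_min, self.r_switch, self.r_max))):
            raise SamplingError("radial bounds must be finite")


#: default radial bounds per (charge class, site-pair kind); "specific"
#: covers HBD/HBA and LB/LA pairings.
RADIAL_TABLE: dict[tuple[str, str], RadialSpec] = {
    ("opposite-charged", "any"): RadialSpec(-1.8, 1.5, 5.0),
    ("like-charged", "any"): RadialSpec(0.0, 2.5, 5.0),
    ("charged/neutral", "general"): RadialSpec(-1.0, 1.5, 5.0),
    ("charged/neutral", "specific"): RadialSpec(-1.6, 1.5, 5.0),
    ("neutral/neutral", "general"): RadialSpec(-1.0, 1.0, 3.0),
    ("neutral/neutral", "specific"): RadialSpec(-1.3, 1.0, 3.0),
}


def radial_spec_for(site_dimer: SiteDimer, table=None) -> RadialSpec:
    table = table if table is not None else RADIAL_TABLE
    cc = site_dimer.charge_class
    if cc in ("opposite-charged", "like-charged"):
        return table[(cc, "any")]
    kind = "general" if site_dimer.pair_class == "general/general" else "specific"
    return table[(cc, kind)]


def sample_r(spec: RadialSpec, rng, upper_override: float | None = None) -> float:
    """Draw from the biased radial density by inverse-CDF.

    Density: constant on [r_min, r_switch], linear to 0 at r_max.  With an
    override U the density is truncated to [r_min, U] and renormalized
    (plain truncation; for U <= r_switch the draw is uniform).
    """
    lo, sw, hi = spec.r_min, spec.r_switch, spec.r_max
    if upper_override is not None:
        if not (lo <= upper_override <= hi):
            raise SamplingError(
                f"upper override {upper_override} outside [{lo}, {hi}]"
            )
        hi_eff = upper_override
    else:
        hi_eff = hi
    if hi_eff <= lo:
        return lo
    if hi_eff <= sw or sw == hi:
        # purely uniform region (triangle absent or cut away)
        return float(rng.uniform(lo, hi_eff))
    w1 = sw - lo
    w2 = hi - sw
    t_u = (hi_eff - sw) / w2  # in (0, 1]
    area = w1 + 0.5 * w2 * (1.0 - (1.0 - t_u) ** 2)
    u = rng.uniform(0.0, area)
    if u <= w1:
        return float(lo + u)
    t = 1.0 - math.sqrt(max(0.0, 1.0 - 2.0 * (u - w1) / w2))
    return float(sw + t * w2)


def radial_pdf(spec: RadialSpec, r) -> np.ndarray:
    """Normalized density of :func:`sample_r` (no override), for checks."""
    r = np.asarray(r, dtype=float)
    lo, sw, hi = spec.r_min, spec.r_switch, spec.r_max
    area = (sw - lo) + 0.5 * (hi - sw)
    out = np.zeros_like(r)
    flat = (r >= lo) & (r <= sw)
    out[flat] = 1.0
    tri = (r > sw) & (r <= hi)
    out[tri] = (hi - r[tri]) / (hi - sw)
    return out / area


def sample_angles(site_P, site_L, rng) -> dict[str, float]:
    """Uniform draws over the sites' interval unions; tau_PL unrestricted."""
    for site in (site_P, site_L):
        if site.theta_range.total_length <= 0 or site.tau_range.total_length <= 0:
            raise SamplingError("empty angular interval union")
    return {
        "theta_P": site_P.theta_range.sample(rng),
        "tau_P": site_P.tau_range.sample(rng),
        "theta_L": site_L.theta_range.sample(rng),
        "tau_L": site_L.tau_range.sample(rng),
        "tau_PL": float(rng.uniform(-180.0, 180.0)),
    }


def perturb_coordinates(config, rng, max_disp: float = 0.1):
    """Displace every atom by a uniformly-oriented vector of uniform length
    in [0, max_disp]; originals retained in ``config.unperturbed``."""
    if max_disp < 0:
        raise SamplingError("max_disp must be >= 0")
    config.unperturbed = (config.protein_coords.copy(), config.ligand_coords.copy())
    if max_disp == 0:
        config.perturbed = True
        return config
    for coords in (config.protein_coords, config.ligand_coords):
        n = coords.shape[0]
        dirs = rng.normal(size=(n, 3))
        norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        # resample degenerate zero vectors deterministically from the stream
        while np.any(norms < 1e-12):
            bad = norms[:, 0] < 1e-12
            dirs[bad] = rng.normal(size=(int(bad.sum()), 3))
            norms = np.linalg.norm(dirs, axis=1, keepdims=True)
        mags = rng.uniform(0.0, max_disp, size=(n, 1))
        coords += dirs / norms * mags
    config.perturbed = True
    return config


@dataclass
class AttemptLog:
    """Acceptance trail for one accepted configuration."""

    attempts: int = 0
    rejected_r: list[float] = field(default_factory=list)
    upper_bounds: list[float | None] = field(default_factory=list)
    threshold: float = 20.0


def rng_for_site_dimer(seed: int, ordinal: int) -> np.random.Generator:
    """Independent Philox sub-stream keyed by (seed, site-dimer ordinal)."""
    return np.random.Generator(np.random.Philox(key=[seed, ordinal]))


def generate_batch(
    site_dimer: SiteDimer,
    backend,
    radii,
    n: int = 50,
    policy: RejectionPolicy | None = None,
    rng: np.random.Generator | None = None,
    radial_table=None,
    max_disp: float = 0.1,
    max_attempts: int = 1000,
):
    """Generate exactly ``n`` accepted configurations for one site dimer.

    Returns (configurations, attempt logs).  Infeasible separations are
    resampled; a backend exception is retried once and then the attempt is
    skipped with a warning.
    """
    import warnings

    policy = policy or RejectionPolicy()
    rng = rng if rng is not None else np.random.default_rng(0)
    spec = radial_spec_for(site_dimer, radial_table)
    threshold = policy.threshold_for(site_dimer.like_charged)

    configs, logs = [], []
    for index in range(n):
        log = AttemptLog(threshold=threshold)
        upper: float | None = None
        r_rejected: float | None = None
        failures = 0
        while True:
            log.attempts += 1
            if log.attempts > max_attempts:
                raise SamplingError(
                    f"no acceptable configuration for {site_dimer.id} "
                    f"after {max_attempts} attempts"
                )
            angles = sample_angles(site_dimer.protein_site, site_dimer.ligand_site, rng)
            r = sample_r(spec, rng, upper_override=upper)
            try:
                r_pl = geometry.solve_translation(
                    site_dimer.protein,
                    site_dimer.ligand,
                    site_dimer.protein_site,
                    site_dimer.ligand_site,
                    angles,
                    r,
                    radii,
                )
            except InfeasibleSeparationError:
                continue  # resample orientation and r
            ic = InternalCoords(r_PL=r_pl, r=r, **angles)
            config = geometry.cartesian_from_internal(
                site_dimer.protein,
                site_dimer.ligand,
                site_dimer.protein_site,
                site_dimer.ligand_site,
                ic,
                site_dimer_id=site_dimer.id,
                index=index,
            )
            perturb_coordinates(config, rng, max_disp=max_disp)
            try:
                record = backend(config)
            except Exception:
                try:
                    record = backend(config)
                except Exception as exc:  # pragma: no cover - defensive
                    warnings.warn(
                        f"energy backend failed twice for {site_dimer.id}: {exc}"
                    )
                    continue
            log.upper_bounds.append(upper)
            if accept_energy(record, site_dimer.like_charged, policy):
                config.energies.append(record)
                configs.append(config)
                logs.append(log)
                break
            failures += 1
            log.rejected_r.append(r)
            if r_rejected is None:
                r_rejected = r
            upper = min(
                spec.r_max, r_rejected + failures * policy.expansion_step
            )
    return configs, logs


def manifest_rows(site_dimer: SiteDimer, configs, logs):
    """JSON-serializable manifest entries for a generated batch."""
    rows = []
    for config, log in zip(configs, logs):
        ic = config.target_internal
        rows.append(
            {
                "site_dimer_id": site_dimer.id,
                "index": config.index,
                "r": ic.r,
                "r_PL": ic.r_PL,
                "theta_P": ic.theta_P,
                "tau_P": ic.tau_P,
                "theta_L": ic.theta_L,
                "tau_L": ic.tau_L,
                "tau_PL": ic.tau_PL,
                "attempts": log.attempts,
                "rejected_r": log.rejected_r,
                "threshold": log.threshold,
                "total_energy": config.energies[0].total if config.energies else None,
            }
        )
    return rows
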
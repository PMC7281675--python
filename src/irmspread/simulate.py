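"""Synthetic IRM spreading movies with full ground truth.

The generator emulates the statistical structure a darker-is-closer IRM
time-lapse of a single spreading platelet: a bright out-of-focus blob while
the platelet hovers above the substrate, thin radial filopodia whose
substrate contact oscillates ("taps") with a period of 5-10 seconds, then a
lamellipodial disk growing logistically to a plateau, all on additive
Gaussian pixel noise.  Contrast is a two-level proximity proxy — touching
pixels are darkened by a fixed amount — not an interference model; the
analysis only consumes monotone darker-is-closer contrast.

Every movie comes with per-pixel ground-truth contact states, the true
phase-onset frames and the drawn tapping periods, so each pipeline stage has
a recoverable target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line
from skimage.morphology import dilation, footprint_rectangle

from .io import BackgroundROI, IRMSequence, PhaseAnnotation, PlateletROI
from .kinetics import make_cohort_table

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_movie",
    "scenario_preset",
    "decimate_sequence",
    "simulate_cohort",
    "PRESETS",
]

PRESETS = ("collagen_like", "fibrinogen_like", "background_only")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic spreading movie.

    Durations are in seconds; the default 1 s frame interval resolves the
    5-10 s tapping oscillation comfortably (use :func:`decimate_sequence`
    to emulate 5 s acquisition and its aliasing).  Intensity parameters are
    in the same arbitrary units as the background mean.
    """

    height: int = 64
    width: int = 64
    frame_interval: float = 1.0
    hover_duration: float = 20.0
    filopodial_duration: float = 60.0
    lamellipodial_duration: float = 60.0
    plateau_duration: float = 40.0
    n_filopodia: int = 6
    filopodium_length: int = 10
    filopodium_width: int = 1
    base_radius: int = 3          # filopodial base / initial disk radius, px
    max_radius: int = 20          # final lamellipodial radius, px
    growth_rate: float = 0.15     # logistic radius growth, 1/s
    tapping_period_range: tuple[float, float] = (5.0, 10.0)
    #: fraction of the filopodial phase over which filopodia appear one by
    #: one, so the tapping activity builds to a peak as the stage completes
    filopodia_stagger: float = 0.5
    contact_darkening: float = 40.0
    #: SD of the residual membrane-height fluctuation of touching pixels,
    #: which keeps the fully spread footprint more active than empty glass
    contact_jitter_sd: float = 2.0
    #: lamellipodial adhesions mature: a newly contacted disk pixel starts at
    #: ``immature_darkening_fraction`` of the full contact darkening and
    #: reaches it after ``maturation_time`` seconds, so the advancing front
    #: keeps producing net attachment signal; tapping contacts stay
    #: all-or-nothing (transient contacts do not mature)
    maturation_time: float = 5.0
    immature_darkening_fraction: float = 0.6
    hover_brightening: float = 3.0   # ~1.5x noise SD: stays on the bright side
    background_mean: float = 100.0
    noise_sd: float = 2.0
    intensity_range: tuple[float, float] = (0.0, 255.0)
    arrest_fraction: float = 0.0  # probability the lamellipodial phase never starts
    scenario: str = "collagen_like"
    seed: int = 0

    def __post_init__(self):
        for name in ("hover_duration", "filopodial_duration",
                     "lamellipodial_duration", "plateau_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tapping_period_range[0] < 2 * self.frame_interval:
            raise ValueError(
                "tapping periods must be >= 2 frame intervals to be "
                "representable (Nyquist)")
        if self.noise_sd > 0 and not self.contact_darkening > 2 * self.noise_sd:
            raise ValueError(
                "contact_darkening must exceed 2x noise SD so contact is "
                "detectable by construction")
        if not 0 <= self.arrest_fraction <= 1:
            raise ValueError("arrest_fraction must be in [0, 1]")
        if self.scenario not in PRESETS:
            raise ValueError(f"unknown scenario {self.scenario!r}")

    @property
    def n_frames_per_phase(self) -> tuple[int, int, int, int]:
        dt = self.frame_interval
        return (int(round(self.hover_duration / dt)),
                int(round(self.filopodial_duration / dt)),
                int(round(self.lamellipodial_duration / dt)),
                int(round(self.plateau_duration / dt)))


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-side truth: contact states, phase onsets and tapping periods."""

    contact: np.ndarray                       # bool (T, H, W)
    filopodia_onset: int | None
    lamellipodia_onset: int | None
    spread_onset: int | None
    tapping_periods: np.ndarray               # seconds, one per filopodium
    filopodium_masks: list[np.ndarray] = field(default_factory=list)
    filopodium_onsets: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=np.int64))  # frame indices
    final_area: int = 0

    def contact_area_trace(self) -> np.ndarray:
        return self.contact.sum(axis=(1, 2)).astype(np.int64)


def _filopodium_footprints(cfg: SimulationConfig, rng: np.random.Generator
                           ) -> list[np.ndarray]:
    """Rasterise each filopodium as a thin radial segment mask."""
    cy, cx = cfg.height // 2, cfg.width // 2
    if cfg.n_filopodia == 0:
        return []
    jitter = rng.uniform(-0.5, 0.5) * 2 * np.pi / cfg.n_filopodia
    angles = jitter + 2 * np.pi * np.arange(cfg.n_filopodia) / cfg.n_filopodia
    masks = []
    for ang in angles:
        r0, r1 = cfg.base_radius, cfg.base_radius + cfg.filopodium_length
        y0 = int(round(cy + r0 * np.sin(ang)))
        x0 = int(round(cx + r0 * np.cos(ang)))
        y1 = int(round(cy + r1 * np.sin(ang)))
        x1 = int(round(cx + r1 * np.cos(ang)))
        rr, cc = draw_line(y0, x0, y1, x1)
        keep = (rr >= 0) & (rr < cfg.height) & (cc >= 0) & (cc < cfg.width)
        m = np.zeros((cfg.height, cfg.width), dtype=bool)
        m[rr[keep], cc[keep]] = True
        if cfg.filopodium_width > 1:
            m = dilation(m, footprint_rectangle(
                (cfg.filopodium_width, cfg.filopodium_width)))
        masks.append(m)
    return masks


def _disk_mask(cfg: SimulationConfig, radius: float) -> np.ndarray:
    cy, cx = cfg.height // 2, cfg.width // 2
    yy, xx = np.ogrid[:cfg.height, :cfg.width]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2


def _logistic_radius(cfg: SimulationConfig, t_seconds: float) -> float:
    """Logistic growth r' = g r (1 - r/R) from the base radius."""
    r0, big_r, g = float(cfg.base_radius), float(cfg.max_radius), cfg.growth_rate
    return big_r / (1.0 + (big_r / r0 - 1.0) * np.exp(-g * t_seconds))


def simulate_movie(cfg: SimulationConfig
                   ) -> tuple[IRMSequence, GroundTruth, PlateletROI,
                              BackgroundROI, PhaseAnnotation]:
    """Render one movie; deterministic for a given config (seed included).

    The random draws happen in a fixed order (tapping periods, tapping
    phases, filopodium angles, arrest decision, pixel noise), so identical
    configs give bit-identical movies.
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.frame_interval
    n_hover, n_fil, n_lam, n_plateau = cfg.n_frames_per_phase

    periods = rng.uniform(*cfg.tapping_period_range, size=cfg.n_filopodia)
    phases = rng.uniform(0, periods) if cfg.n_filopodia else np.empty(0)
    filo_masks = _filopodium_footprints(cfg, rng)
    arrested = bool(rng.uniform() < cfg.arrest_fraction)

    if cfg.scenario == "background_only":
        n_hover = n_fil = n_lam = 0
        n_plateau = max(sum(cfg.n_frames_per_phase), 2)
        filo_masks, periods = [], np.empty(0)
        arrested = False
        grow_disk = False
        n_cycle = 0
    elif arrested:
        # filopodial cycling continues for the whole movie; no disk ever grows
        n_cycle = n_fil + n_lam + n_plateau
        n_fil, n_lam, n_plateau = n_cycle, 0, 0
        grow_disk = False
    else:
        n_cycle = n_fil
        grow_disk = n_lam > 0

    t_total = n_hover + n_fil + n_lam + n_plateau
    if t_total < 2:
        raise ValueError("configured durations give fewer than 2 frames")

    fil_onset = n_hover if n_fil > 0 else None
    lam_onset = n_hover + n_fil if grow_disk else None
    spread_onset = n_hover + n_fil + n_lam if (grow_disk and n_plateau > 0) else None

    # filopodia appear one by one over the first `filopodia_stagger` part of
    # the filopodial phase, so total tapping activity builds to a peak
    if cfg.n_filopodia and fil_onset is not None:
        appear = fil_onset + np.floor(
            cfg.filopodia_stagger * n_fil
            * np.arange(cfg.n_filopodia) / cfg.n_filopodia).astype(np.int64)
    else:
        appear = np.empty(0, dtype=np.int64)

    contact = np.zeros((t_total, cfg.height, cfg.width), dtype=bool)
    # per-pixel-frame darkening amount; disk pixels ramp up as the adhesion
    # matures, everything else is all-or-nothing at full darkening
    darkening = np.zeros((t_total, cfg.height, cfg.width), dtype=np.float64)
    disk_first_contact = np.full((cfg.height, cfg.width), -1, dtype=np.int64)
    d_full = cfg.contact_darkening
    f_imm = cfg.immature_darkening_fraction
    mat_frames = max(cfg.maturation_time / dt, 1e-9)
    for t in range(t_total):
        if t < n_hover:
            continue
        frame = np.zeros((cfg.height, cfg.width), dtype=bool)
        if fil_onset is not None and t < n_hover + n_fil:
            for f, mask in enumerate(filo_masks):
                if t < appear[f]:
                    continue
                tau = (t - appear[f]) * dt
                if ((tau + phases[f]) % periods[f]) < periods[f] / 2:
                    frame |= mask
            darkening[t][frame] = d_full
        elif lam_onset is not None:
            tau = (t - lam_onset) * dt
            tau_end = (n_lam - 1) * dt
            r = _logistic_radius(cfg, min(tau, tau_end))
            disk = _disk_mask(cfg, r)
            new = disk & (disk_first_contact < 0)
            disk_first_contact[new] = t
            age = (t - disk_first_contact) / mat_frames
            ramp = np.clip(f_imm + (1.0 - f_imm) * age, f_imm, 1.0)
            darkening[t][disk] = d_full * ramp[disk]
            frame = disk.copy()
            for mask in filo_masks:   # filopodia stabilise once spreading starts
                frame |= mask
            darkening[t][frame & ~disk] = d_full  # matured during tapping
        contact[t] = frame

    movie = cfg.background_mean + rng.normal(
        0.0, cfg.noise_sd, size=(t_total, cfg.height, cfg.width))
    if n_hover > 0 and cfg.scenario != "background_only":
        cy, cx = cfg.height // 2, cfg.width // 2
        yy, xx = np.ogrid[:cfg.height, :cfg.width]
        blob = cfg.hover_brightening * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 8.0 ** 2))
        movie[:n_hover] += blob[None]
    movie -= darkening
    if cfg.contact_jitter_sd > 0 and contact.any():
        # residual membrane-height fluctuation of touching pixels
        jitter = rng.normal(0.0, cfg.contact_jitter_sd,
                            size=(t_total, cfg.height, cfg.width))
        movie[contact] += jitter[contact]
    np.clip(movie, *cfg.intensity_range, out=movie)
    movie = movie.astype(np.float32)

    seq = IRMSequence(movie, frame_interval=dt,
                      source_id=f"sim:{cfg.scenario}:seed={cfg.seed}")

    gt = GroundTruth(
        contact=contact,
        filopodia_onset=fil_onset,
        lamellipodia_onset=lam_onset,
        spread_onset=spread_onset,
        tapping_periods=periods,
        filopodium_masks=filo_masks,
        filopodium_onsets=appear,
        final_area=int(contact[-1].sum()),
    )

    roi, bg = _choose_rois(cfg, contact)
    if not contact.any():
        endpoint = "no_attach"
    elif grow_disk:
        endpoint = "fully_spread"
    else:
        endpoint = "filopodial"
    ann = PhaseAnnotation(
        platelet_id=f"sim-{cfg.scenario}-{cfg.seed}",
        onset_frame=0,
        filopodia_onset_frame=fil_onset,
        lamellipodia_onset_frame=lam_onset,
        spread_frame=spread_onset,
        endpoint_class=endpoint,
    )
    ann.validate_against(roi)
    return seq, gt, roi, bg, ann


def _choose_rois(cfg: SimulationConfig, contact: np.ndarray
                 ) -> tuple[PlateletROI, BackgroundROI]:
    """Bounding box of the full footprint (+margin), and a disjoint empty box."""
    margin = 3
    any_contact = contact.any(axis=0)
    if any_contact.any():
        rows = np.flatnonzero(any_contact.any(axis=1))
        cols = np.flatnonzero(any_contact.any(axis=0))
        box = (max(0, rows[0] - margin), max(0, cols[0] - margin),
               min(cfg.height, rows[-1] + 1 + margin),
               min(cfg.width, cols[-1] + 1 + margin))
    else:
        cy, cx = cfg.height // 2, cfg.width // 2
        half = min(cfg.height, cfg.width) // 4
        box = (cy - half, cx - half, cy + half, cx + half)
    roi = PlateletROI(platelet_id=f"sim-{cfg.scenario}-{cfg.seed}",
                      box=box, frame_range=(0, contact.shape[0]))

    bg_size = 8
    for r0, c0 in [(0, 0), (0, cfg.width - bg_size),
                   (cfg.height - bg_size, 0),
                   (cfg.height - bg_size, cfg.width - bg_size)]:
        bg = BackgroundROI((r0, c0, r0 + bg_size, c0 + bg_size))
        if bg.disjoint_from(roi):
            return roi, bg
    raise ValueError("no empty background region disjoint from the platelet box; "
                     "increase the image size")


def scenario_preset(name: str, *, seed: int = 0, **overrides) -> SimulationConfig:
    """Named study conditions.

    ``collagen_like``: the full phase script — hover, filopodial tapping,
    lamellipodial growth to a plateau.  ``fibrinogen_like``: prolonged
    whole-filopodium attach/detach cycling; with probability 0.57 (the
    arrest fraction) the lamellipodial phase never starts.
    ``background_only``: pixel noise only, no platelet.
    """
    if name == "collagen_like":
        cfg = SimulationConfig(scenario="collagen_like", seed=seed)
    elif name == "fibrinogen_like":
        cfg = SimulationConfig(scenario="fibrinogen_like", seed=seed,
                               filopodial_duration=120.0,
                               arrest_fraction=0.57)
    elif name == "background_only":
        cfg = SimulationConfig(scenario="background_only", seed=seed,
                               n_filopodia=0)
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of {PRESETS}")
    return replace(cfg, **overrides) if overrides else cfg


def decimate_sequence(seq: IRMSequence, factor: int) -> IRMSequence:
    """Keep every ``factor``-th frame, emulating slower acquisition.

    With 1 s simulation frames and factor 5 this reproduces the 5 s
    acquisition interval; tapping periods near 2x the new interval alias.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    frames = seq.frames[::factor]
    if frames.shape[0] < 2:
        raise ValueError("decimation leaves fewer than 2 frames")
    return IRMSequence(frames, frame_interval=seq.frame_interval * factor,
                       origin_time=seq.origin_time,
                       source_id=f"{seq.source_id}:dec{factor}")


# ---------------------------------------------------------------------------
# cohort-level synthesis


#: median attachment times (s) of the default synthetic cohorts; the
#: collagen-like surface binds twice as fast, consistent in direction with
#: the faster attachment observed on collagen IV
COHORT_MEDIANS = {"collagen_iv": 60.0, "fibrinogen": 120.0}


def simulate_cohort(n_per_substrate: dict[str, int],
                    rng: np.random.Generator | int | None = None,
                    *, horizon: float = 3600.0,
                    medians: dict[str, float] | None = None) -> pd.DataFrame:
    """Draw a synthetic cohort of attachment times.

    Attachment times are exponential with the given per-substrate median;
    platelets not attached by ``horizon`` seconds are censored at the
    horizon.  Returns a cohort table usable by the kinetics functions.
    """
    rng = np.random.default_rng(rng)
    medians = dict(COHORT_MEDIANS if medians is None else medians)
    records = []
    for substrate, n in n_per_substrate.items():
        scale = medians[substrate] / np.log(2.0)
        times = rng.exponential(scale, size=n)
        for i, t in enumerate(times):
            censored = bool(t > horizon)
            records.append({
                "platelet_id": f"{substrate}-{i}",
                "substrate": substrate,
                "attachment_time": horizon if censored else float(t),
                "censored": censored,
                "filopodial_duration": np.nan,
                "lamellipodial_duration": np.nan,
                "endpoint_class": "no_attach" if censored else "fully_spread",
            })
    return make_cohort_table(records)
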
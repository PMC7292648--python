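"""Study-condition configuration objects for the synthetic cortex generator.

The defaults encode the conditions of a 3-week cuprizone demyelination /
9-week recovery time course imaged weekly in a 425 x 425 x 300 um cortical
volume: depth-increasing oligodendrocyte density, a loss-hazard schedule
peaking just after cuprizone withdrawal (cumulative ~94% of baseline), and a
zone-resolved addition schedule that bursts early in recovery and decays to
~3.5% of baseline per week (volume-wide cumulative ~55% at recovery week 9).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

__all__ = [
    "VolumeSpec",
    "CohortConfig",
    "MorphologyConfig",
    "AxonFieldConfig",
    "PunctaConfig",
    "default_cohort",
    "default_morphology",
    "default_axon_field",
    "default_puncta",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class VolumeSpec:
    """Imaged volume geometry, in micrometres from the pial surface.

    ``zone_edges`` delimit half-open depth zones [lo, hi) used for
    depth-resolved counting; voxel pitches define the rasterization grid
    for territory analysis (anisotropic by default: 1 um in x-y, 3 um in z).
    """

    x_extent: float = 425.0
    y_extent: float = 425.0
    z_extent: float = 300.0
    zone_edges: tuple = (0.0, 100.0, 200.0, 300.0)
    xy_voxel: float = 1.0
    z_voxel: float = 3.0

    def __post_init__(self):
        if min(self.x_extent, self.y_extent, self.z_extent) <= 0:
            raise ValueError("volume extents must be positive")
        if self.xy_voxel <= 0 or self.z_voxel <= 0:
            raise ValueError("voxel pitches must be positive")
        edges = tuple(self.zone_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("zone_edges must be strictly increasing")
        if edges and (edges[0] < 0 or edges[-1] > self.z_extent + 1e-9):
            raise ValueError("zone_edges must lie within [0, z_extent]")

    @property
    def n_zones(self) -> int:
        return len(self.zone_edges) - 1


# Weekly hazard of loss for baseline cells (keyed by imaging week).
# Cumulative loss 1 - prod(1-h) = 94.2% of baseline, with most loss after
# cuprizone withdrawal at week 3.
CUPRIZONE_LOSS_SCHEDULE = {1: 0.01, 2: 0.03, 3: 0.35, 4: 0.70, 5: 0.6903}

# Shape of the addition burst over recovery weeks 1..9 (imaging weeks 4..12):
# rapid early oligodendrogenesis that decays to ~3.5%/week.  Normalized per
# zone to the cumulative targets below.
ADDITION_SHAPE = {4: 4.0, 5: 12.0, 6: 11.0, 7: 8.0, 8: 6.0,
                  9: 5.0, 10: 4.0, 11: 3.7, 12: 3.5}

# Cumulative addition (fraction of zone baseline) over 9 recovery weeks:
# regeneration is efficient superficially, impaired at depth.
CUPRIZONE_ZONE_ADDITION = (0.794, 0.558, 0.497)

# Control mice gain cells slowly at a roughly constant proportional rate.
CONTROL_WEEKLY_ADDITION = (0.0262, 0.0275, 0.0293)


def _cuprizone_addition_schedule() -> tuple:
    total = sum(ADDITION_SHAPE.values())
    return tuple(
        {wk: cum * s / total for wk, s in ADDITION_SHAPE.items()}
        for cum in CUPRIZONE_ZONE_ADDITION
    )


def _control_addition_schedule(weeks: Sequence[int]) -> tuple:
    return tuple(
        {wk: rate for wk in weeks if wk > 0}
        for rate in CONTROL_WEEKLY_ADDITION
    )


@dataclass(frozen=True)
class CohortConfig:
    """One virtual cohort: session plan, demography and noise model.

    ``loss_schedule`` maps imaging week -> per-cell hazard of a baseline
    cell disappearing at that week.  ``addition_schedule`` is one dict per
    depth zone mapping week -> new cells that week as a fraction of the
    zone's baseline count.  ``drift_sd`` is the per-axis SD of the rigid
    per-session registration offset; ``jitter_sd`` the per-axis SD of
    i.i.d. detection noise.  New cells are placed at a radial distance
    ``displacement_min`` + Lognormal(mean ``displacement_mean`` -
    ``displacement_min``, log-sd ``displacement_sigma``) from a uniformly
    chosen reference cell: regenerated cells appear in distinctly new
    positions, clearly separated from the registration wobble scale.
    """

    n_mice: int = 6
    condition: str = "cuprizone"
    session_weeks: tuple = tuple(range(13))
    baseline_density_by_zone: tuple = (17, 40, 79)
    loss_schedule: dict = field(default_factory=dict)
    addition_schedule: tuple = ()
    loss_phase_end: int = 5
    final_week: int = 12
    drift_sd: float = 3.0
    jitter_sd: float = 2.0
    displacement_min: float = 12.0
    displacement_mean: float = 30.0
    displacement_sigma: float = 0.6

    def __post_init__(self):
        if self.condition not in ("control", "cuprizone"):
            raise ValueError(f"unknown condition {self.condition!r}")
        weeks = tuple(self.session_weeks)
        if len(weeks) == 0:
            raise ValueError("session_weeks must be non-empty")
        if any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ValueError("session_weeks must be strictly increasing")
        if any(h < 0 for h in self.loss_schedule.values()):
            raise ValueError("loss hazards must be non-negative")
        for sched in self.addition_schedule:
            if any(r < 0 for r in sched.values()):
                raise ValueError("addition rates must be non-negative")


def default_cohort(condition: str = "cuprizone", **overrides) -> CohortConfig:
    """Paper-calibrated default cohort for either condition."""
    weeks = tuple(range(13))
    if condition == "cuprizone":
        cfg = dict(
            condition="cuprizone",
            session_weeks=weeks,
            loss_schedule=dict(CUPRIZONE_LOSS_SCHEDULE),
            addition_schedule=_cuprizone_addition_schedule(),
        )
    else:
        cfg = dict(
            condition="control",
            session_weeks=weeks,
            loss_schedule={},
            addition_schedule=_control_addition_schedule(weeks),
        )
    cfg.update(overrides)
    return CohortConfig(**cfg)


@dataclass(frozen=True)
class MorphologyConfig:
    """Single-cell arbor statistics for newly formed oligodendrocytes.

    Counts and lengths are between-cell / between-sheath SDs (not SEMs).
    Lengths are drawn from a right-skewed distribution (lognormal default).
    The arbor is an axially symmetric ellipsoid around the soma; with
    ``radial_isotropy`` sheath azimuths are uniform in the x-y plane.
    """

    sheath_count_mean: float = 53.0
    sheath_count_sd: float = 8.0
    sheath_length_mean: float = 62.6
    sheath_length_sd: float = 25.0
    length_dist: str = "lognormal"
    arbor_xy_radius: float = 76.0
    arbor_z_radius: float = 30.0
    radial_isotropy: bool = True
    point_spacing: float = 2.0
    prune_fraction: float = 0.1
    mature_day: int = 14

    def __post_init__(self):
        if self.sheath_count_mean <= 0 or self.sheath_length_mean <= 0:
            raise ValueError("means must be positive")
        if self.arbor_xy_radius <= 0 or self.arbor_z_radius <= 0:
            raise ValueError("arbor radii must be positive")
        if self.length_dist not in ("lognormal", "gamma"):
            raise ValueError(f"unknown length_dist {self.length_dist!r}")


def default_morphology(condition: str = "control", **overrides) -> MorphologyConfig:
    if condition == "control":
        cfg = {}
    elif condition in ("cuprizone", "regenerated"):
        cfg = dict(sheath_count_mean=51.0, sheath_length_mean=72.3,
                   arbor_xy_radius=85.0)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    cfg.update(overrides)
    return MorphologyConfig(**cfg)


@dataclass(frozen=True)
class AxonFieldConfig:
    """Field of intermittently myelinated axons with session-resolved fates.

    Axons carry runs of 1-3 consecutive internodes separated by short node
    gaps (<5 um), runs separated by long bare stretches.  Baseline
    internodes are destroyed with ``destroy_prob``; destroyed internodes are
    replaced (coverage >= ``replace_coverage_min`` of the baseline interval
    by a new-cell sheath) with a probability conditional on their baseline
    neighbor class.  Novel internodes appear on bare stretches in proportion
    to the baseline count.
    """

    extent: float = 150.0
    n_axons: int = 250
    internode_length_mean: float = 62.6
    internode_length_sd: float = 20.0
    node_gap_range: tuple = (0.5, 3.0)
    bare_gap_range: tuple = (25.0, 80.0)
    run_length_probs: tuple = (0.5704, 0.2296, 0.20)
    destroy_prob: float = 0.844
    replace_prob_by_class: tuple = (0.3505, 0.732, 0.732)
    novel_rate: float = 0.476
    replace_coverage_min: float = 0.55
    replace_coverage_max: float = 0.95
    point_spacing: float = 2.0

    def __post_init__(self):
        if self.destroy_prob < 0 or self.destroy_prob > 1:
            raise ValueError("destroy_prob must be a probability")
        for p in self.replace_prob_by_class:
            if p < 0 or p > 1:
                raise ValueError("replacement probabilities must be in [0,1]")
        if abs(sum(self.run_length_probs) - 1.0) > 1e-6:
            raise ValueError("run_length_probs must sum to 1")


def default_axon_field(condition: str = "cuprizone", **overrides) -> AxonFieldConfig:
    if condition == "cuprizone":
        cfg = {}
    elif condition == "control":
        # Internodes are almost perfectly stable; new oligodendrogenesis
        # still adds a substantial fraction of novel sheaths.
        cfg = dict(destroy_prob=0.009,
                   replace_prob_by_class=(0.0, 0.0, 0.0),
                   novel_rate=0.258)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    cfg.update(overrides)
    return AxonFieldConfig(**cfg)


@dataclass(frozen=True)
class PunctaConfig:
    """Nodal (betaIV-spectrin) / paranodal (Caspr) puncta field statistics.

    ``flank_probs`` = probability a nodal punctum retains (2, 1, 0)
    paranodal partners within the pairing radius; demyelination shifts mass
    toward 0.  ``ais_fraction`` of nodal structures are elongated (>6 um)
    AIS-like objects to be excluded by the size filter.
    """

    field_xy: float = 135.0
    field_z: float = 30.0
    n_nodal: int = 300
    flank_probs: tuple = (0.85, 0.10, 0.05)
    partner_distance_range: tuple = (0.8, 3.0)
    stray_paranodal_fraction: float = 0.2
    ais_fraction: float = 0.15
    ais_length_range: tuple = (8.0, 25.0)
    punctum_length_range: tuple = (0.5, 2.0)
    min_separation: float = 8.0

    def __post_init__(self):
        if self.n_nodal < 0:
            raise ValueError("densities must be non-negative")
        if abs(sum(self.flank_probs) - 1.0) > 1e-6:
            raise ValueError("flank_probs must sum to 1")


# Flanking-probability presets by condition and cuprizone duration (weeks),
# mirroring the progressive stripping of paranodes with longer exposure.
PUNCTA_PRESETS = {
    ("control", 4): (0.85, 0.10, 0.05),
    ("control", 6): (0.85, 0.10, 0.05),
    ("cuprizone", 4): (0.45, 0.25, 0.30),
    ("cuprizone", 6): (0.10, 0.15, 0.75),
}


def default_puncta(condition: str = "control", duration_weeks: int = 6,
                   **overrides) -> PunctaConfig:
    key = (condition, duration_weeks)
    if key not in PUNCTA_PRESETS:
        raise ValueError(f"no puncta preset for {key}")
    n_nodal = 300 if condition == "control" else (220 if duration_weeks == 4 else 140)
    cfg = dict(flank_probs=PUNCTA_PRESETS[key], n_nodal=n_nodal)
    cfg.update(overrides)
    return PunctaConfig(**cfg)


_CONFIG_TYPES = {
    "volume": VolumeSpec,
    "cohort": CohortConfig,
    "morphology": MorphologyConfig,
    "axon_field": AxonFieldConfig,
    "puncta": PunctaConfig,
}


def save_config(path, **sections) -> None:
    """Write dataclass config sections to a YAML key-value file."""
    doc = {}
    for name, obj in sections.items():
        doc[name] = asdict(obj) if hasattr(obj, "__dataclass_fields__") else obj
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _coerce(cls, data: dict):
    # YAML round-trips tuples as lists; coerce back where fields expect them
    kwargs = {}
    for name, f in cls.__dataclass_fields__.items():
        if name not in data:
            continue
        val = data[name]
        if isinstance(val, list):
            val = tuple(tuple(v) if isinstance(v, list)
                        else (dict(v) if isinstance(v, dict) else v)
                        for v in val)
        kwargs[name] = val
    return cls(**kwargs)


def load_config(path) -> dict:
    """Read a YAML config; returns {section: dataclass-or-dict}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    for name, data in doc.items():
        cls = _CONFIG_TYPES.get(name)
        out[name] = _coerce(cls, data) if cls and isinstance(data, dict) else data
    return out
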
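"""Bundled simulation scenarios.

Two scenarios exercise the full pipeline end to end at desk scale:

``null``
    No temperature effect is programmed anywhere: every agent's
    lag-1-temperature attraction slope is zero.  Every downstream model
    should find flat fold changes and no significant smooths.

``lag1-effect``
    Subordinate species A is given a positive lag-1 attraction slope
    toward the zone shared with the dominant predator (its attraction
    probability is logistic(-2.2 + 1.2 * z(T_{d-1}))); subordinate B's
    slope is zero.  Encounter and spatial-overlap models should recover
    a lag-1 effect for pair A only.

The scenario covers one six-month dry season with two individuals per
species; the dominant animals anchor on the shared zone, subordinate A
ranges ~2.5 km away (so the programmed pull measurably changes its
overlap), subordinate B the same distance on the opposite side.  The
slope of 1.2 was chosen at design time to make the programmed effect
comfortably recoverable at this scale.
"""

from __future__ import annotations

from datetime import date

from .synthetic import AgentSpec, WorldConfig

SCENARIOS = ("null", "lag1-effect")


def scenario_config(name: str, seed: int = 0) -> tuple[WorldConfig, list[AgentSpec]]:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
    slope_a = 1.2 if name == "lag1-effect" else 0.0
    cfg = WorldConfig(
        extent=(0.0, 0.0, 16_000.0, 16_000.0),
        raster_resolution=10.0,
        start=date(2015, 5, 1),
        end=date(2015, 10, 31),
        sampling_interval_minutes=15.0,
        shared_zone=(8_000.0, 8_000.0, 800.0),
        seed=seed,
    )
    zone = (8_000.0, 8_000.0)
    agents = []
    for i, off in enumerate([(-300.0, 0.0), (300.0, 200.0)]):
        agents.append(
            AgentSpec(
                individual_id=f"dom{i + 1}",
                species="lion",
                role="dominant",
                group_id=f"pride{i + 1}",
                home_center=(zone[0] + off[0], zone[1] + off[1]),
                home_scale=900.0,
                shared_zone_attraction_base=-0.5,
                temp_lag1_attraction_slope=0.0,
                diel_amplitude=0.7,
                diel_peak_hour=1.0,
                step_shape=2.0,
                step_scale=120.0,
            )
        )
    for i, off in enumerate([(-2500.0, -600.0), (-2300.0, 900.0)]):
        agents.append(
            AgentSpec(
                individual_id=f"subA{i + 1}",
                species="cheetah",
                role="subordinate_a",
                group_id=f"chA{i + 1}",
                home_center=(zone[0] + off[0], zone[1] + off[1]),
                home_scale=1100.0,
                shared_zone_attraction_base=-2.2,
                temp_lag1_attraction_slope=slope_a,
                diel_amplitude=0.7,
                diel_peak_hour=13.0,
                step_shape=2.0,
                step_scale=150.0,
            )
        )
    for i, off in enumerate([(2500.0, 600.0), (2300.0, -900.0)]):
        agents.append(
            AgentSpec(
                individual_id=f"subB{i + 1}",
                species="wild_dog",
                role="subordinate_b",
                group_id=f"packB{i + 1}",
                home_center=(zone[0] + off[0], zone[1] + off[1]),
                home_scale=1100.0,
                shared_zone_attraction_base=-2.2,
                temp_lag1_attraction_slope=0.0,
                diel_amplitude=0.5,
                diel_peak_hour=7.0,
                step_shape=2.0,
                step_scale=150.0,
            )
        )
    return cfg, agents
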
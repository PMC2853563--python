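"""Seeded generators for clone tables and induction cohorts.

The null generator draws clone centres uniformly on the unit rhombomere and
radii from the lognormal radius distribution, independently — exactly the
structure the null model assumes.  The restricted generator embodies
boundary restriction as truncation-to-abutment: a clone whose radius would
carry it over the nearest boundary is, with probability ``beta``, stopped at
the boundary (its radius truncated to the boundary distance, turning it into
a respecter).  ``beta = 0`` reproduces the null draw-for-draw; ``beta = 1``
eliminates crossing entirely.  Truncation is a modelling choice of this
package: it reproduces the qualitative signature of restriction (excess
respecters, deficit of crossers) with a single parameter, not a mechanism
claim.

The cohort generator emulates induction experiments: per embryo a Bernoulli
recombination event, and for recombined embryos a Bernoulli hindbrain
localisation, summarised per experimental group as the total induction
frequency F and the hindbrain frequency HB F.

Determinism: every generator is a pure function of its config.  Streams are
derived from the root seed with ``SeedSequence(seed, spawn_key=(stream_id,))``
(clones = 0, cohort = 1, fixtures = 2), so adding a generator never perturbs
existing output.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clone_data, inference, null_model
from .clone_data import CloneRecord

__all__ = [
    "SimulationConfig",
    "GroupSpec",
    "CohortConfig",
    "TABLE1_GROUPS",
    "simulate_null_clones",
    "simulate_restricted_clones",
    "simulate_induction_cohort",
    "generate_fixtures",
    "table_to_records",
]

_STREAMS = {"clones": 0, "cohort": 1, "fixtures": 2}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named stream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimulationConfig:
    """Config for clone-table simulation.

    Defaults state the analysed world: 116 bounded clones pooled into one
    idealised rhombomere with radii lognormal(mu = -1.34, sigma = 0.64).
    Raw lengths a, b, c are emitted in units where the rhombomere is
    ``rhombomere_length_units`` long; the default 128 is a power of two so
    that de-normalization and re-normalization round-trip bit-exactly in
    floating point.  ``beta`` is the boundary-restriction strength
    (0 = null); ``delta`` the classification margin used when a category
    column is requested downstream.
    """

    n_clones: int = 116
    mu: float = null_model.DEFAULT_MU
    sigma: float = null_model.DEFAULT_SIGMA
    beta: float = 0.0
    delta: float = 0.0
    seed: int = 0
    rhombomere_length_units: float = 128.0

    def __post_init__(self):
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must lie in [0, 1]")
        if not (0.0 <= self.delta < 0.5):
            raise ValueError("delta must lie in [0, 0.5)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.rhombomere_length_units <= 0:
            raise ValueError("rhombomere_length_units must be > 0")


def _simulate_clones(config: SimulationConfig, beta: float) -> pd.DataFrame:
    """Core draw shared by the null and restricted generators.

    The random stream consumes (x, r, u) in a fixed order regardless of
    beta, so beta = 0 is draw-for-draw identical to the null generator.
    """
    rng = stream_rng(config.seed, "clones")
    n = config.n_clones
    x = rng.uniform(size=n)
    r = rng.lognormal(config.mu, config.sigma, size=n)
    u = rng.uniform(size=n)
    d = np.minimum(x, 1.0 - x)
    truncated = (r > d) & (u < beta)
    r = np.where(truncated, d, r)
    units = config.rhombomere_length_units
    return pd.DataFrame(
        {
            "embryo_id": [f"sim{i:05d}" for i in range(n)],
            "rhombomere": "pooled",
            "a": x * units,
            "b": np.full(n, units),
            "c": 2.0 * r * units,
            "x": x,
            "r": r,
            "truncated": truncated,
        }
    )


def simulate_null_clones(config: SimulationConfig) -> pd.DataFrame:
    """Null clone table: uniform positions, lognormal radii, no boundary effect.

    Requires ``config.beta == 0``.  Returns one row per clone with raw
    lengths (a, b, c) and the normalized (x, r) they de-normalize from; the
    pair round-trips exactly through :func:`clone_data.normalize_clone`.
    """
    if config.beta != 0.0:
        raise ValueError("null simulation requires beta = 0; use simulate_restricted_clones")
    return _simulate_clones(config, beta=0.0)


def simulate_restricted_clones(config: SimulationConfig) -> pd.DataFrame:
    """Clone table under boundary restriction of strength ``config.beta``.

    Would-be crossers are truncated to abutment with probability beta (the
    ``truncated`` column flags them).  beta = 0 equals the null table at the
    same seed."""
    return _simulate_clones(config, beta=config.beta)


def table_to_records(table: pd.DataFrame) -> list[CloneRecord]:
    """Convert a simulated table to :class:`CloneRecord` objects."""
    return [
        CloneRecord(
            embryo_id=row.embryo_id,
            rhombomere=row.rhombomere,
            a=row.a,
            b=row.b,
            c=row.c,
        )
        for row in table.itertuples()
    ]


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: induction/observation stages (dpc), size, rates."""

    stage_induced: float
    stage_observed: float
    n_embryos: int
    p_recombination: float
    p_hindbrain_given_recombination: float

    def __post_init__(self):
        if self.n_embryos <= 0:
            raise ValueError("n_embryos must be positive")
        for name in ("p_recombination", "p_hindbrain_given_recombination"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")


#: Default cohort: the five published experimental groups, with each group's
#: total induction frequency as p_recombination and the ratio HB F / F as the
#: conditional hindbrain probability.
TABLE1_GROUPS = (
    GroupSpec(5.5, 9.5, 128, 0.5391, 0.2422 / 0.5391),
    GroupSpec(5.5, 10.5, 106, 0.1981, 0.0849 / 0.1981),
    GroupSpec(6.5, 10.5, 23, 0.6522, 0.1739 / 0.6522),
    GroupSpec(7.5, 10.5, 83, 0.9518, 0.3976 / 0.9518),
    GroupSpec(8.5, 10.5, 63, 0.9365, 0.3175 / 0.9365),
)


@dataclass(frozen=True)
class CohortConfig:
    """Config for induction-cohort simulation; defaults emulate the published groups."""

    groups: tuple[GroupSpec, ...] = TABLE1_GROUPS
    seed: int = 0

    def __post_init__(self):
        if len(self.groups) == 0:
            raise ValueError("at least one group is required")


def simulate_induction_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate recombination events per embryo and summarise per group.

    Per embryo: Bernoulli(p_recombination) for any recombination event, then
    Bernoulli(p_hindbrain_given_recombination) for the event lying in the
    hindbrain (hindbrain events are a subset of all events by construction).
    Returns ``(embryos, summary)``; the summary has one row per group with
    F = events / n and HB F = hindbrain events / n.
    """
    rng = stream_rng(config.seed, "cohort")
    embryo_rows = []
    summary_rows = []
    for g_idx, g in enumerate(config.groups):
        recombined = rng.uniform(size=g.n_embryos) < g.p_recombination
        hb_draw = rng.uniform(size=g.n_embryos) < g.p_hindbrain_given_recombination
        hindbrain = recombined & hb_draw
        for i in range(g.n_embryos):
            embryo_rows.append(
                {
                    "group": g_idx,
                    "stage_induced": g.stage_induced,
                    "stage_observed": g.stage_observed,
                    "embryo_id": f"g{g_idx}e{i:04d}",
                    "recombined": bool(recombined[i]),
                    "hindbrain": bool(hindbrain[i]),
                }
            )
        summary_rows.append(
            {
                "group": g_idx,
                "stage_induced": g.stage_induced,
                "stage_observed": g.stage_observed,
                "n": g.n_embryos,
                "events": int(recombined.sum()),
                "hb_events": int(hindbrain.sum()),
                "F": recombined.mean(),
                "HB_F": hindbrain.mean(),
            }
        )
    return pd.DataFrame(embryo_rows), pd.DataFrame(summary_rows)


FIXTURE_SEED = 20100412


def generate_fixtures(output_dir: str | Path, seed: int = FIXTURE_SEED) -> dict:
    """Write the documented fixture set and its manifest; idempotent.

    Produces ``null_clones_n116.tsv`` (null, n = 116), ``restricted_clones_
    n116_beta08.tsv`` (restriction strength 0.8), ``cohort.tsv`` (per-group
    induction summary) and ``manifest.json`` holding summary values
    (category counts at the calibrated margin, assumption-check p-values,
    goodness-of-fit results) computed from the written tables.  Running
    twice with the same seed rewrites identical files.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = null_model.LognormalRadiusModel()
    delta = model.calibrate_delta(0.22)
    probs = model.category_probabilities(delta)

    manifest: dict = {"seed": seed, "delta": delta, "files": {}}
    tables = {
        "null_clones_n116.tsv": simulate_null_clones(
            SimulationConfig(seed=seed, delta=delta)
        ),
        "restricted_clones_n116_beta08.tsv": simulate_restricted_clones(
            SimulationConfig(seed=seed, beta=0.8, delta=delta)
        ),
    }
    for name, table in tables.items():
        path = outdir / name
        records = table_to_records(table)
        clone_data.write_clone_table(records, path)
        cats = clone_data.classify_positions_radii(
            table["x"].to_numpy(), table["r"].to_numpy(), delta
        )
        counts = clone_data.CategoryCounts(
            n_cross=int((cats == clone_data.CROSS).sum()),
            n_respect=int((cats == clone_data.RESPECT).sum()),
            n_middle=int((cats == clone_data.MIDDLE).sum()),
        )
        gof = inference.chisq_gof(counts, probs)
        manifest["files"][name] = {
            "n": len(records),
            "counts": {
                "cross": counts.n_cross,
                "respect": counts.n_respect,
                "middle": counts.n_middle,
            },
            "gof_chi2": gof.chi2,
            "gof_p_value": gof.p_value,
            "ks_uniform_p": inference.ks_uniform_positions(table["x"]).p_value,
            "ks_lognormal_p": inference.ks_lognormal_radii(table["r"], model).p_value,
            "size_position_correlation": inference.size_position_correlation(
                table["x"], table["r"]
            ),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    _, summary = simulate_induction_cohort(CohortConfig(seed=seed))
    cohort_path = outdir / "cohort.tsv"
    summary.to_csv(cohort_path, sep="\t", index=False, float_format="%.17g")
    manifest["files"]["cohort.tsv"] = {
        "n_embryos": int(summary["n"].sum()),
        "total_F": float(summary["events"].sum() / summary["n"].sum()),
        "total_HB_F": float(summary["hb_events"].sum() / summary["n"].sum()),
        "sha256": hashlib.sha256(cohort_path.read_bytes()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
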
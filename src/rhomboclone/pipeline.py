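"""End-to-end analysis run: clone table in, report directory out.

Composes the modules: read/normalize the clone table, fit or fix the
lognormal radius model, calibrate or fix the classification margin, tally
categories, run the trinomial goodness-of-fit against the null model, run
the assumption checks, and write the crossing-probability curves.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, clone_data, inference, null_model
from .clone_data import CategoryCounts, CROSS
from .null_model import LognormalRadiusModel

logger = logging.getLogger("rhomboclone")

__all__ = ["RunConfig", "run_pipeline", "gof_from_counts"]


@dataclass
class RunConfig:
    """Serializable configuration of one analysis run.

    ``mu``/``sigma`` default to None, meaning the model is fitted from the
    observed radii (the standard route).  ``delta`` is either a float margin
    or the string ``"calibrate:<target>"``, which calibrates the margin so
    the null respect probability equals ``<target>`` (default target 0.22).
    ``counts`` allows running the goodness-of-fit from pre-tallied
    (cross, respect, middle) counts with the default model, with no
    clone-level data; ``probabilities`` then optionally fixes the null
    (cross, respect, middle) probabilities directly — the route for
    reproducing published tables whose expected counts were computed from
    rounded probabilities.
    """

    input_path: str | None = None
    counts: tuple[int, int, int] | None = None  # (cross, respect, middle)
    probabilities: tuple[float, float, float] | None = None  # counts mode only
    mu: float | None = None
    sigma: float | None = None
    delta: float | str = "calibrate:0.22"
    smoother_df: int = 8
    circular: bool = True
    bin_width: float = 0.1
    seed: int = 0
    strict: bool = True
    output_dir: str = "rhomboclone_report"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "counts" in data and data["counts"] is not None:
            data["counts"] = tuple(int(v) for v in data["counts"])
        if "probabilities" in data and data["probabilities"] is not None:
            data["probabilities"] = tuple(float(v) for v in data["probabilities"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("counts", "probabilities"):
            if data[key] is not None:
                data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _resolve_model_and_delta(
    config: RunConfig, radii: np.ndarray | None
) -> tuple[LognormalRadiusModel, float]:
    if config.mu is not None and config.sigma is not None:
        model = LognormalRadiusModel(mu=config.mu, sigma=config.sigma)
        how = "fixed by config"
    elif radii is not None:
        model = null_model.fit_lognormal(radii)
        how = "fitted from observed radii"
    else:
        model = LognormalRadiusModel()
        how = "package defaults"
    logger.info("model: mu=%.4f sigma=%.4f (%s)", model.mu, model.sigma, how)
    if isinstance(config.delta, str):
        if not config.delta.startswith("calibrate:"):
            raise ValueError(f"unrecognized delta policy {config.delta!r}")
        target = float(config.delta.split(":", 1)[1])
        delta = model.calibrate_delta(target)
        logger.info("delta calibrated to %.6f (target p_respect=%.4f)", delta, target)
    else:
        delta = float(config.delta)
        logger.info("delta fixed at %.6f", delta)
    return model, delta


def gof_from_counts(
    counts: CategoryCounts,
    model: LognormalRadiusModel | None = None,
    delta: float | str = "calibrate:0.22",
    probabilities: tuple[float, float, float] | None = None,
) -> inference.GofResult:
    """Goodness-of-fit of pre-tallied counts against a null model.

    Convenience for published-table reproduction where no clone-level data
    exist.  ``delta`` as in :class:`RunConfig`.  Passing ``probabilities``
    (cross, respect, middle) bypasses the model, e.g. to use a table's
    printed rounded probabilities.
    """
    if probabilities is not None:
        probs = null_model.CategoryProbabilities(*probabilities)
    else:
        model = model or LognormalRadiusModel()
        if isinstance(delta, str):
            target = float(delta.split(":", 1)[1])
            delta = model.calibrate_delta(target)
        probs = model.category_probabilities(delta)
    return inference.chisq_gof(counts, probs)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full analysis and write the report directory.

    Writes: ``normalized.tsv`` (clone table with x, r, category columns),
    ``counts.tsv``, ``gof.tsv`` (observed/expected/discrepancy layout),
    ``checks.tsv`` (KS uniformity, KS lognormality, size-position
    correlation), ``curves.tsv`` (theoretical, binned, smoothed on one
    grid), and ``run_config.yaml`` + ``run_log.txt`` recording every
    parameter.  In counts-only mode only gof.tsv and the log are written.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run_log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("rhomboclone %s", __version__)
        if config.counts is not None:
            counts = CategoryCounts(*config.counts)
            if config.probabilities is not None:
                probs = null_model.CategoryProbabilities(*config.probabilities)
                logger.info("null probabilities fixed by config: %s", config.probabilities)
            else:
                model, delta = _resolve_model_and_delta(config, None)
                probs = model.category_probabilities(delta)
            gof = inference.chisq_gof(counts, probs)
            gof.as_frame().to_csv(outdir / "gof.tsv", sep="\t", index=False)
            logger.info("gof: chi2=%.1f df=%d %s", gof.chi2, gof.df, gof.p_label())
        else:
            if config.input_path is None:
                raise ValueError("config needs input_path or counts")
            records = clone_data.read_clone_table(
                config.input_path, strict=config.strict
            )
            logger.info("read %d clone records from %s", len(records), config.input_path)
            bounded = [
                rec for rec in records if rec.observed_category != clone_data.UNBOUNDED
            ]
            norm = [clone_data.normalize_clone(rec) for rec in bounded]
            x = np.array([nc.x for nc in norm])
            r = np.array([nc.r for nc in norm])
            model, delta = _resolve_model_and_delta(config, r)

            frame = clone_data.records_to_frame(records, delta=delta)
            frame.to_csv(outdir / "normalized.tsv", sep="\t", index=False)

            counts = clone_data.count_categories(records, delta)
            pd.DataFrame(
                [
                    {
                        "n_cross": counts.n_cross,
                        "n_respect": counts.n_respect,
                        "n_middle": counts.n_middle,
                        "n_unbounded": counts.n_unbounded,
                        "n_total": counts.n_total,
                    }
                ]
            ).to_csv(outdir / "counts.tsv", sep="\t", index=False)

            gof = inference.chisq_gof(counts, model.category_probabilities(delta))
            gof.as_frame().to_csv(outdir / "gof.tsv", sep="\t", index=False)
            logger.info("gof: chi2=%.1f df=%d %s", gof.chi2, gof.df, gof.p_label())

            ks_u = inference.ks_uniform_positions(x)
            ks_l = inference.ks_lognormal_radii(r, model)
            corr = inference.size_position_correlation(x, r)
            pd.DataFrame(
                [
                    {"check": "ks_uniform_positions", "statistic": ks_u.statistic, "p_value": ks_u.p_value},
                    {"check": "ks_lognormal_radii", "statistic": ks_l.statistic, "p_value": ks_l.p_value},
                    {"check": "size_position_correlation", "statistic": corr, "p_value": float("nan")},
                ]
            ).to_csv(outdir / "checks.tsv", sep="\t", index=False)
            logger.info(
                "checks: KS-uniform p=%.3g, KS-lognormal p=%.3g, corr=%.3f",
                ks_u.p_value, ks_l.p_value, corr,
            )

            cats = frame.loc[frame["category"] != clone_data.UNBOUNDED, "category"]
            is_cross = (cats == CROSS).to_numpy()
            theo = inference.theoretical_curve(model)
            binned = inference.binned_crossing_fraction(x, is_cross, config.bin_width)
            smoothed = inference.smooth_crossing_probability(
                x, is_cross, smoother_df=config.smoother_df, circular=config.circular
            )
            curves = pd.DataFrame({"x": theo.grid, "theoretical": theo.p})
            curves["smoothed"] = np.interp(theo.grid, smoothed.grid, smoothed.p)
            # step curve: constant within each bin, NaN where empty
            bin_idx = np.clip(
                np.digitize(theo.grid, binned.bin_edges) - 1, 0, len(binned.p) - 1
            )
            curves["binned"] = binned.p[bin_idx]
            curves.to_csv(outdir / "curves.tsv", sep="\t", index=False)
            logger.info("curves written (smoother_df=%d, circular=%s)",
                        config.smoother_df, config.circular)
        config.to_yaml(outdir / "run_config.yaml")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return outdir
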
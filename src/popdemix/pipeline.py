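"""End-to-end pipeline: simulate -> dpca -> decode -> distance -> compare-variance.

A single JSON-serializable :class:`PipelineConfig` drives every stage; every
stochastic stage carries an explicit seed, and the summary JSON is written
with sorted keys so identical configs produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .designs import DESIGN_FACTORIES, MARGINALIZATION_LABELS, PARAMETER, TaskDesign
from .decoding import decode_timecourse, significance_intervals
from .distance import bootstrap_bands, randomization_compare
from .dpca import fit_dpca, project_conditions
from .io import write_csv, write_hdf5
from .recording import PopulationRecording, build_rate_tensor
from .stats import chi2_compare
from .synthetic import EffectSpec, generate_population, planted_fractions

log = logging.getLogger("popdemix")

ALL_STAGES = ("simulate", "dpca", "decode", "distance", "compare_variance")


@dataclass
class PipelineConfig:
    """Configuration of a full run; round-trips losslessly through JSON."""

    design: dict | str = "reach_direction"
    n_neurons: int = 50
    effect: dict = field(
        default_factory=lambda: {
            "target_fractions": {
                "condition_independent": 0.58,
                "parameter": 0.24,
                "visual": 0.11,
                "interaction": 0.07,
            }
        }
    )
    stages: tuple[str, ...] = ALL_STAGES
    seeds: dict = field(
        default_factory=lambda: {"simulate": 0, "decode": 1, "distance": 2}
    )
    output_dir: str = "popdemix_run"
    q_per_marginalization: int = 10
    reg: object = "auto"
    decode_target: str = PARAMETER
    decode_iterations: int = 25
    decode_shuffles: int = 25
    distance_bootstrap: int = 50
    distance_randomization: int = 50
    min_consecutive: int = 10
    alpha: float = 0.05

    def resolve_design(self) -> TaskDesign:
        if isinstance(self.design, str):
            return DESIGN_FACTORIES[self.design]()
        return TaskDesign.from_dict(self.design)

    def to_json(self, path) -> None:
        d = asdict(self)
        d["stages"] = list(self.stages)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        return cls(**d)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns (and writes) the summary dict.

    Every stage writes tidy CSV/JSON outputs under ``config.output_dir``;
    a failure aborts with the stage name in the exception.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.resolve_design()
    summary: dict = {
        "design": design.to_dict(),
        "n_neurons": config.n_neurons,
        "seeds": dict(config.seeds),
        "stages": list(config.stages),
    }
    recording: PopulationRecording | None = None
    tensor = None
    stage = "setup"
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            spec = EffectSpec(**config.effect, seed=int(config.seeds.get("simulate", 0)))
            recording = generate_population(design, config.n_neurons, spec)
            write_csv(recording, out / "population.csv")
            write_hdf5(recording, out / "population.h5")
            sidecar = {
                "design": design.to_dict(),
                "n_neurons": config.n_neurons,
                "seed": spec.seed,
                "planted_fractions": planted_fractions(spec, design),
                "noise_model": spec.noise_model,
                "baseline_hz": spec.baseline_hz,
                "signal_std_hz": spec.signal_std_hz,
            }
            with open(out / "population.json", "w") as fh:
                json.dump(_json_ready(sidecar), fh, indent=2, sort_keys=True)
                fh.write("\n")
            summary["planted_fractions"] = planted_fractions(spec, design)
            log.info("simulate: N=%d S=%d V=%d T=%d seed=%d", config.n_neurons,
                     design.n_parameter_levels, design.n_visual_levels,
                     design.n_bins, spec.seed)

        if recording is not None and any(
            s in config.stages for s in ("dpca", "decode", "distance", "compare_variance")
        ):
            tensor = build_rate_tensor(recording)

        if "dpca" in config.stages:
            stage = "dpca"
            result = fit_dpca(tensor, config.q_per_marginalization, config.reg)
            split = result.variance_split
            pd.DataFrame(
                {
                    "component": np.arange(result.n_components),
                    "marginalization": result.marginalization_of_component,
                    "variance_pct": 100 * result.component_variances,
                }
            ).to_csv(out / "components.csv", index=False)
            proj = project_conditions(result, tensor)
            rows = []
            d = design
            for j in range(min(result.n_components, 8)):
                for s, p_level in enumerate(d.parameter_levels):
                    for v, v_level in enumerate(d.visual_levels):
                        for t in range(d.n_bins):
                            rows.append(
                                (j, p_level, v_level, t, proj[j, s, v, t])
                            )
            pd.DataFrame(
                rows,
                columns=["component", "parameter_level", "visual_level", "bin", "value"],
            ).to_csv(out / "projections.csv", index=False, float_format="%.17g")
            summary["variance_split_pct"] = {k: round(v, 6) for k, v in split.items()}
            summary["cumulative_variance_dpca"] = result.cumulative_variance_dpca
            summary["cumulative_variance_pca"] = result.cumulative_variance_pca
            summary["reg"] = result.reg

        if "decode" in config.stages:
            stage = "decode"
            res = decode_timecourse(
                tensor,
                target=config.decode_target,
                n_iterations=config.decode_iterations,
                seed=int(config.seeds.get("decode", 0)),
            )
            res = significance_intervals(
                tensor,
                res,
                n_shuffles=config.decode_shuffles,
                alpha=config.alpha,
                min_consecutive=config.min_consecutive,
            )
            pd.DataFrame(
                {
                    "bin": np.arange(res.accuracy.shape[0]),
                    "accuracy": res.accuracy,
                    "null_q95": res.null_threshold,
                    "significant": res.accuracy > res.null_threshold,
                }
            ).to_csv(out / "decoding.csv", index=False, float_format="%.17g")
            with open(out / "decoding_intervals.json", "w") as fh:
                json.dump(_json_ready(res.significant_intervals), fh)
                fh.write("\n")
            summary["decoding"] = {
                "target": res.target,
                "mean_accuracy": float(res.accuracy.mean()),
                "chance_level": res.chance_level,
                "significant_intervals": res.significant_intervals,
            }

        if "distance" in config.stages:
            stage = "distance"
            dres = bootstrap_bands(
                tensor,
                n_bootstrap=config.distance_bootstrap,
                seed=int(config.seeds.get("distance", 0)),
                min_consecutive=config.min_consecutive,
            )
            rres = randomization_compare(
                tensor,
                n_iter=config.distance_randomization,
                alpha=config.alpha,
                seed=int(config.seeds.get("distance", 0)) + 1,
                min_consecutive=config.min_consecutive,
            )
            T = dres.parameter_curve.shape[0]
            frames = []
            for name, curve, band in (
                ("parameter", dres.parameter_curve, dres.parameter_ci),
                ("visual", dres.visual_curve, dres.visual_ci),
            ):
                frames.append(
                    pd.DataFrame(
                        {
                            "bin": np.arange(T),
                            "curve": name,
                            "value": curve,
                            "ci_lo": band[0],
                            "ci_hi": band[1],
                        }
                    )
                )
            pd.concat(frames).to_csv(
                out / "distance.csv", index=False, float_format="%.17g"
            )
            with open(out / "distance_intervals.json", "w") as fh:
                json.dump(
                    _json_ready(
                        {
                            "ci_separation": dres.separation_intervals,
                            "randomization": rres.randomization_intervals,
                        }
                    ),
                    fh,
                )
                fh.write("\n")
            summary["distance"] = {
                "separation_intervals": dres.separation_intervals,
                "randomization_intervals": rres.randomization_intervals,
            }

        if "compare_variance" in config.stages:
            stage = "compare_variance"
            if "variance_split_pct" not in summary:
                split = {
                    k: v for k, v in
                    fit_dpca(tensor, config.q_per_marginalization, config.reg).variance_split.items()
                }
                summary["variance_split_pct"] = {k: round(v, 6) for k, v in split.items()}
            split = summary["variance_split_pct"]
            cmp = chi2_compare(
                [split["visual"], split["parameter"]],
                labels=("visual", "parameter"),
                alpha=config.alpha,
            )
            pd.DataFrame(
                [
                    {
                        "labels": "|".join(cmp.labels),
                        "percentages": "|".join(f"{p:g}" for p in cmp.percentages),
                        "chi2": cmp.chi2,
                        "dof": cmp.dof,
                        "p_value": cmp.p_value,
                        "significant": cmp.significant,
                    }
                ]
            ).to_csv(out / "variance_comparison.csv", index=False)
            summary["variance_comparison"] = {
                "chi2": cmp.chi2,
                "dof": cmp.dof,
                "p_value": cmp.p_value,
                "significant": cmp.significant,
            }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(_json_ready(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
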
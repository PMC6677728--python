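"""End-to-end orchestration: simulate/load -> perceive -> stats -> expression.

All outputs are plain text (CSV + JSON + a human-readable report) and are
byte-reproducible for a fixed seed and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import ModelFit, fit_binomial_glm, fit_lm, trials_to_frame
from .expression import (
    HEAD_TISSUE,
    beta_regression,
    dermal_proportion_table,
    expression_table,
    stage_contrast,
)
from .simulate import (
    ChoiceGenParams,
    QpcrGenParams,
    SpectrumGenParams,
    default_qpcr_params,
    simulate_choice_trials,
    simulate_colour_experiment,
    simulate_qpcr,
)
from .spectra import individual_means, read_metadata, read_spectra, resample_1nm, spectra_to_long
from .vision import (
    bluetit,
    catch_vector,
    discriminate,
    load_viewer,
    perceptual_summary,
)

logger = logging.getLogger(__name__)

ACHROMATIC_TREATMENTS = ("black", "white")
CHROMATIC_TREATMENTS = ("brown", "green")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str | Path = "camovis_run"
    seed: int = 0
    spectra_path: str | Path | None = None  # None -> simulate
    metadata_path: str | Path | None = None
    trials_path: str | Path | None = None  # None -> simulate
    qpcr_path: str | Path | None = None  # None -> simulate
    viewer: str = "bluetit"  # built-in name or path to a YAML viewer file
    aggregate: str = "individual"  # individual | measurement
    anova_type: int = 2
    log10_responses: bool = True
    spectrum_params: SpectrumGenParams = field(default_factory=SpectrumGenParams)
    choice_params: ChoiceGenParams = field(default_factory=ChoiceGenParams)
    qpcr_params: QpcrGenParams = field(default_factory=default_qpcr_params)
    design: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("black", "control"): 29,
            ("black", "painted"): 45,
            ("white", "control"): 26,
            ("white", "painted"): 49,
            ("brown", "control"): 44,
            ("brown", "painted"): 50,
            ("green", "control"): 36,
            ("green", "painted"): 31,
        }
    )

    def validate(self) -> None:
        if self.aggregate not in ("individual", "measurement"):
            raise ValueError("aggregate must be 'individual' or 'measurement'")
        if self.anova_type not in (1, 2):
            raise ValueError("anova_type must be 1 or 2")
        for name in ("spectra_path", "metadata_path", "trials_path", "qpcr_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} does not exist: {path}")
        if (self.spectra_path is None) != (self.metadata_path is None):
            raise ValueError("spectra_path and metadata_path must be given together")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        simple = {
            "out_dir", "seed", "spectra_path", "metadata_path", "trials_path",
            "qpcr_path", "viewer", "aggregate", "anova_type", "log10_responses",
        }
        for key in simple & set(raw):
            kwargs[key] = raw[key]
        if "spectrum_params" in raw:
            kwargs["spectrum_params"] = SpectrumGenParams(**raw["spectrum_params"])
        if "choice_params" in raw:
            kwargs["choice_params"] = ChoiceGenParams(**raw["choice_params"])
        if "qpcr_params" in raw:
            kwargs["qpcr_params"] = QpcrGenParams(**raw["qpcr_params"])
        if "design" in raw:
            kwargs["design"] = {
                (d["treatment"], d["blindfold"]): int(d["n"]) for d in raw["design"]
            }
        return cls(**kwargs)

    def canonical(self) -> str:
        """Stable text rendering used for the manifest hash."""
        d = {  # out_dir excluded: output location is not part of the analysis
            "seed": self.seed,
            "spectra_path": str(self.spectra_path) if self.spectra_path else None,
            "metadata_path": str(self.metadata_path) if self.metadata_path else None,
            "trials_path": str(self.trials_path) if self.trials_path else None,
            "qpcr_path": str(self.qpcr_path) if self.qpcr_path else None,
            "viewer": self.viewer,
            "aggregate": self.aggregate,
            "anova_type": self.anova_type,
            "log10_responses": self.log10_responses,
            "spectrum_params": vars(self.spectrum_params),
            "choice_params": {
                "diagonal_sizes": {f"{k[0]}|{k[1]}": v for k, v in self.choice_params.diagonal_sizes.items()},
                "horizontal_sizes": {f"{k[0]}|{k[1]}": v for k, v in self.choice_params.horizontal_sizes.items()},
                "p_match": self.choice_params.p_match
                if not isinstance(self.choice_params.p_match, dict)
                else {f"{k[0]}|{k[1]}": v for k, v in self.choice_params.p_match.items()},
                "position_effect": self.choice_params.position_effect,
            },
            "qpcr_params": {
                "ref_mean_cp": self.qpcr_params.ref_mean_cp,
                "true_ratios": {f"{k[0]}|{k[1]}|{k[2]}": v for k, v in self.qpcr_params.true_ratios.items()},
                "replicate_sd": self.qpcr_params.replicate_sd,
                "n_samples_per_stage": self.qpcr_params.n_samples_per_stage,
            },
            "design": {f"{k[0]}|{k[1]}": v for k, v in self.design.items()},
        }
        return json.dumps(d, sort_keys=True)


def _get_viewer(name_or_path: str):
    if name_or_path in ("bluetit", "bluetit-ideal"):
        return bluetit("ideal" if name_or_path.endswith("ideal") else "d65")
    return load_viewer(name_or_path)


def _term_rows(name: str, fit: ModelFit) -> list[dict]:
    rows = []
    for term, vals in fit.terms.iterrows():
        row = {"model": name, "term": term, "n": fit.n_obs, "df_resid": fit.df_resid}
        row.update({k: vals.get(k, np.nan) for k in ("estimate", "se", "F", "df1", "df2", "z", "t", "p_value")})
        rows.append(row)
    return rows


def perceive(
    spectra_table,
    metadata: pd.DataFrame,
    viewer,
    aggregate: str = "individual",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spectra + metadata -> perceptual summaries and larva-vs-dowel JND."""
    meta = metadata.set_index("individual_id")
    if aggregate == "individual":
        spectra = individual_means(spectra_table)
    else:  # every measurement kept as its own pseudo-individual
        spectra = {
            col: resample_1nm(spectra_table, col) for col in spectra_table.columns
        }
    summaries = []
    for ind, spec in spectra.items():
        base_id = ind.rsplit("_", 1)[0] if aggregate == "measurement" else ind
        if base_id not in meta.index:
            raise KeyError(f"individual {base_id!r} missing from metadata")
        info = meta.loc[base_id]
        s = perceptual_summary(spec, viewer, individual_id=ind)
        summaries.append(
            {
                "individual_id": ind,
                "treatment": info["treatment"],
                "blindfold": info["blindfold"],
                "life_stage": info.get("life_stage", "larva"),
                "greenness": s.greenness,
                "luminance": s.luminance,
                "tetra_x": s.tetra.x,
                "tetra_y": s.tetra.y,
                "tetra_z": s.tetra.z,
            }
        )
    summary_df = pd.DataFrame(summaries)

    # larva-vs-own-treatment-dowel discriminability
    dowel_catches = {}
    for ind, spec in spectra.items():
        base_id = ind.rsplit("_", 1)[0] if aggregate == "measurement" else ind
        if meta.loc[base_id].get("life_stage", "larva") == "dowel":
            dowel_catches[meta.loc[base_id]["treatment"]] = catch_vector(spec, viewer)
    jnd_rows = []
    for ind, spec in spectra.items():
        base_id = ind.rsplit("_", 1)[0] if aggregate == "measurement" else ind
        info = meta.loc[base_id]
        if info.get("life_stage", "larva") == "dowel":
            continue
        treatment = info["treatment"]
        if treatment not in dowel_catches:
            continue
        res = discriminate(catch_vector(spec, viewer), dowel_catches[treatment], viewer)
        jnd_rows.append(
            {
                "id_a": ind,
                "id_b": f"dowel-{treatment}",
                "treatment": treatment,
                "blindfold": info["blindfold"],
                "jnd_chromatic": res.jnd_chromatic,
                "jnd_achromatic": res.jnd_achromatic,
                "class_chromatic": res.class_chromatic,
                "class_achromatic": res.class_achromatic,
            }
        )
    return summary_df, pd.DataFrame(jnd_rows)


def colour_models(
    summary_df: pd.DataFrame,
    jnd_df: pd.DataFrame,
    anova_type: int = 2,
    log10_responses: bool = True,
) -> dict[str, ModelFit]:
    """The four colour-response linear models."""
    larvae = summary_df[summary_df["life_stage"] == "larva"]
    achrom = larvae[larvae["treatment"].isin(ACHROMATIC_TREATMENTS)]
    chrom = larvae[larvae["treatment"].isin(CHROMATIC_TREATMENTS)]
    jnd_achrom = jnd_df[jnd_df["treatment"].isin(ACHROMATIC_TREATMENTS)]
    jnd_chrom = jnd_df[jnd_df["treatment"].isin(CHROMATIC_TREATMENTS)]
    fits = {}
    for name, df, response in (
        ("luminance", achrom, "luminance"),
        ("greenness", chrom, "greenness"),
        ("jnd_achromatic", jnd_achrom, "jnd_achromatic"),
        ("jnd_chromatic", jnd_chrom, "jnd_chromatic"),
    ):
        if df.empty:
            continue  # design without this treatment pair
        factors = [f for f in ("treatment", "blindfold") if df[f].nunique() > 1]
        if not factors:
            continue
        fits[name] = fit_lm(
            df, response, factors, log10=log10_responses, anova_type=anova_type
        )
    return fits


def choice_models(trials_df: pd.DataFrame) -> dict[str, ModelFit]:
    fits = {}
    diagonal = trials_df[trials_df["arena"] == "diagonal"]
    horizontal = trials_df[trials_df["arena"] == "horizontal"]
    if len(diagonal) >= 10:
        fits["choice_diagonal"] = fit_binomial_glm(diagonal, ["larval_colour", "blindfold"])
    if len(horizontal) >= 10:
        fits["choice_horizontal"] = fit_binomial_glm(
            horizontal, ["larval_colour", "blindfold", "dowel_position"]
        )
    return fits


def expression_models(qpcr_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, ModelFit]]:
    ratios = expression_table(qpcr_df)
    proportions = dermal_proportion_table(ratios)
    fits: dict[str, ModelFit] = {}
    head = ratios[ratios["tissue"] == HEAD_TISSUE]
    # dermal expression averaged across body segments per sample x gene
    dermal = (
        ratios[ratios["tissue"] != HEAD_TISSUE]
        .groupby(["sample", "stage", "gene"], sort=False)["ratio"]
        .mean()
        .reset_index()
    )
    fits["head_stage_contrast"] = stage_contrast(head)
    fits["dermal_stage_contrast"] = stage_contrast(dermal)
    fits["dermal_proportion_beta"] = beta_regression(proportions, predictor="stage")
    return ratios, proportions, fits


def _report_lines(all_fits: dict[str, ModelFit]) -> list[str]:
    lines = ["camovis run report", "=" * 40]
    for name, fit in all_fits.items():
        lines.append("")
        lines.append(f"model: {name} ({fit.family}, n={fit.n_obs}, df_resid={fit.df_resid})")
        for term, vals in fit.terms.iterrows():
            parts = [f"  {term}:"]
            if "F" in vals and np.isfinite(vals.get("df1", np.nan)):
                parts.append(
                    f"F_{int(vals['df1'])},{int(vals['df2'])} = {vals['F']:.4g}"
                )
            elif "F" in vals and not np.isnan(vals.get("F", np.nan)):
                parts.append(f"F = {vals['F']:.4g}")
            if "z" in vals and not np.isnan(vals.get("z", np.nan)):
                parts.append(f"estimate = {vals['estimate']:.4g}, Z = {vals['z']:.4g}")
            if "t" in vals and not np.isnan(vals.get("t", np.nan)):
                parts.append(f"estimate = {vals['estimate']:.4g}, t_{fit.df_resid} = {vals['t']:.4g}")
            if not np.isnan(vals.get("p_value", np.nan)):
                parts.append(f"P = {vals['p_value']:.4g}")
            lines.append(" ".join(parts))
        for note in fit.notes:
            lines.append(f"  note: {note}")
        if fit.separation_flag:
            lines.append("  note: separation flag raised")
    return lines


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the output bundle; returns the fits."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_fits: dict[str, ModelFit] = {}

    def _stage(name, fn, *args, **kwargs):
        logger.info("stage %s: start", name)
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineError(name, str(exc)) from exc
        logger.info("stage %s: done", name)
        return result

    # --- inputs ---------------------------------------------------------
    if config.spectra_path is not None:
        spectra_table = _stage("read_spectra", read_spectra, config.spectra_path)
        metadata = _stage("read_metadata", read_metadata, config.metadata_path)
    else:
        spectra_wide, metadata = _stage(
            "simulate_spectra",
            simulate_colour_experiment,
            config.design,
            config.spectrum_params,
            config.seed,
        )
        spectra_csv = out / "simulated_spectra.csv"
        spectra_wide.to_csv(spectra_csv, index=False)
        metadata.to_csv(out / "simulated_metadata.csv", index=False)
        spectra_table = _stage("read_spectra", read_spectra, spectra_csv)

    if config.trials_path is not None:
        trials_df = pd.read_csv(config.trials_path)
    else:
        trials = _stage("simulate_choice", simulate_choice_trials, config.choice_params, config.seed)
        trials_df = trials_to_frame(trials)
        trials_df.to_csv(out / "simulated_trials.csv", index=False)

    if config.qpcr_path is not None:
        qpcr_df = pd.read_csv(config.qpcr_path)
    else:
        qpcr_df = _stage("simulate_qpcr", simulate_qpcr, config.qpcr_params, config.seed)
        qpcr_df.to_csv(out / "simulated_qpcr.csv", index=False)

    # --- perceive -------------------------------------------------------
    viewer = _stage("viewer", _get_viewer, config.viewer)
    summary_df, jnd_df = _stage(
        "perceive", perceive, spectra_table, metadata, viewer, config.aggregate
    )
    mean_spectra = _stage("spectra_means", individual_means, spectra_table)
    spectra_to_long(mean_spectra).to_csv(out / "mean_spectra.csv", index=False)
    summary_df.to_csv(out / "perceptual_summary.csv", index=False)
    jnd_df.to_csv(out / "discrimination.csv", index=False)

    # --- statistics -----------------------------------------------------
    all_fits.update(
        _stage(
            "colour_models",
            colour_models,
            summary_df,
            jnd_df,
            config.anova_type,
            config.log10_responses,
        )
    )
    all_fits.update(_stage("choice_models", choice_models, trials_df))
    ratios, proportions, expr_fits = _stage("expression", expression_models, qpcr_df)
    all_fits.update(expr_fits)
    ratios.to_csv(out / "expression_ratios.csv", index=False)
    proportions.to_csv(out / "dermal_proportions.csv", index=False)

    term_rows: list[dict] = []
    for name, fit in all_fits.items():
        term_rows.extend(_term_rows(name, fit))
    pd.DataFrame(term_rows).to_csv(out / "model_terms.csv", index=False)

    # --- report + manifest ---------------------------------------------
    (out / "report.txt").write_text("\n".join(_report_lines(all_fits)) + "\n")
    manifest = {
        "config_sha256": hashlib.sha256(config.canonical().encode()).hexdigest(),
        "seed": config.seed,
        "camovis_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return all_fits
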
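"""End-to-end orchestration: generate/load -> z-score -> rank -> RCI ->
decompose -> change -> report files.

``run_pipeline`` drives the whole analysis for one or two survey rounds and
writes all artifacts (per-round RCI JSON, decomposition CSV + JSON,
change-decomposition CSV + JSON, concentration-curve CSV, run log).  The
decomposition stages are complete-case: rows missing any model variable are
dropped with a logged count; the RCI stage uses all rows with an observed
outcome, optionally adding a multiple-imputation estimate.  Weights are
normalized within round; every stochastic stage logs its seed, and the
in-run additivity identities are verified before any file is written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bayes import McmcConfig, contribution_intervals, gibbs_regression
from .change import format_table4, oaxaca_change
from .concentration import ConcentrationIndex
from .decompose import WagstaffDecomposition, format_table3
from .errors import ConfigError, SchemaError
from .generate import GeneratorConfig, generate_survey
from .impute import ImputationConfig, rci_with_imputation
from .io import read_survey_csv, write_curve_csv, write_json, write_survey_csv
from .model import MODEL_COLUMNS, build_design
from .standardize import AgeZScorer

logger = logging.getLogger("cogineq")

_ADDITIVITY_TOL = 1e-10


@dataclass
class PipelineConfig:
    """Full-pipeline configuration (see ``from_dict`` for the JSON schema)."""

    rounds: list[dict]  # each: {"label": str} + {"generator": {...}} or {"path": str}
    output_dir: str = "cogineq_out"
    contributors: list[str] = field(default_factory=lambda: list(MODEL_COLUMNS))
    outcome: str = "z"
    ranking: str = "log_pce"
    weight: str = "weight"
    round_col: str = "round"
    ties: str = "stable"
    seed: int = 0
    mcmc: dict | None = None
    imputation: dict | None = None
    oaxaca_variant: str = "current_elasticity"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ConfigError("rounds must list at least one round")
        if len(self.rounds) > 2:
            raise ConfigError("the change stage needs exactly two rounds; got more")
        for r in self.rounds:
            if "label" not in r:
                raise ConfigError("every round needs a 'label'")
            if ("generator" in r) == ("path" in r):
                raise ConfigError(
                    f"round {r.get('label')!r} needs exactly one of 'generator' or 'path'"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        try:
            return cls(**d)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def _load_round(round_spec: dict, seed: int) -> pd.DataFrame:
    if "generator" in round_spec:
        gcfg = dict(round_spec["generator"])
        gcfg.setdefault("seed", seed)
        gcfg.setdefault("round_label", round_spec["label"])
        return generate_survey(GeneratorConfig.from_dict(gcfg))
    return read_survey_csv(round_spec["path"])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest of written artifact paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"pipeline seed: {config.seed}"]
    manifest: dict[str, str] = {}

    tables = []
    for i, round_spec in enumerate(config.rounds):
        round_seed = config.seed + i
        t = _load_round(round_spec, round_seed)
        if "generator" in round_spec:
            log_lines.append(f"round {round_spec['label']}: generated with seed {round_seed}")
            path = outdir / f"survey_{round_spec['label']}.csv"
            write_survey_csv(t, path)
            manifest[f"survey_{round_spec['label']}"] = str(path)
        needed = set(config.contributors) | {
            config.ranking, config.weight, config.round_col, "raw_score", "age"
        }
        absent = sorted(needed - set(t.columns))
        if absent:
            raise SchemaError(f"round {round_spec['label']!r}: columns not in data: {absent}")
        tables.append((round_spec["label"], t))

    # z-scores are fit per round on all rows with observed score and age
    full = pd.concat([t for _, t in tables], ignore_index=True)
    zscorer = AgeZScorer(round_col=config.round_col).fit(full)
    (outdir / "zscore_model.json").write_text(zscorer.to_json(indent=2))
    manifest["zscore_model"] = str(outdir / "zscore_model.json")

    decompositions = {}
    for label, t in tables:
        t = zscorer.transform(t)
        n_in = len(t)

        # RCI on all rows with observed outcome/ranking/weight
        rci_rows = t.dropna(subset=[config.outcome, config.ranking, config.weight])
        est = ConcentrationIndex(ties=config.ties).fit(
            rci_rows[config.outcome].to_numpy(float),
            rci_rows[config.ranking].to_numpy(float),
            rci_rows[config.weight].to_numpy(float),
        )
        rci_payload = {"complete_case": est.result_().to_dict()}
        write_curve_csv(est.sample_, outdir / f"curve_{label}.csv")
        manifest[f"curve_{label}"] = str(outdir / f"curve_{label}.csv")

        if config.imputation is not None:
            icfg = ImputationConfig(**config.imputation)
            pooled = rci_with_imputation(
                t,
                icfg,
                outcome=config.outcome,
                ranking=config.ranking,
                weight=config.weight,
                ties=config.ties,
            )
            rci_payload["multiple_imputation"] = pooled.to_dict()
            log_lines.append(
                f"round {label}: MI with m={icfg.m}, cycles={icfg.cycles}, seed={icfg.seed}"
            )
        write_json(rci_payload, outdir / f"rci_{label}.json")
        manifest[f"rci_{label}"] = str(outdir / f"rci_{label}.json")

        # complete-case decomposition
        model_cols = [config.outcome, config.ranking, config.weight] + config.contributors
        cc = t.dropna(subset=sorted(set(model_cols)))
        n_cc = len(cc)
        log_lines.append(
            f"round {label}: rows in={n_in}, complete-case analyzed={n_cc}, "
            f"excluded for missing model variables={n_in - n_cc}"
        )
        X = build_design(cc, config.contributors)
        dec = WagstaffDecomposition(ties=config.ties).fit(
            X,
            cc[config.outcome].to_numpy(float),
            cc[config.ranking].to_numpy(float),
            cc[config.weight].to_numpy(float),
            label=label,
        )
        result = dec.result_
        gap = result.additivity_gap()
        if gap > _ADDITIVITY_TOL:
            raise AssertionError(
                f"round {label}: decomposition additivity violated (gap {gap:.3e})"
            )
        log_lines.append(f"round {label}: additivity gap {gap:.3e}")

        cis = None
        if config.mcmc is not None:
            mcfg = McmcConfig(**{**config.mcmc, "seed": config.mcmc.get("seed", config.seed)})
            draws = gibbs_regression(
                cc[config.outcome].to_numpy(float), X, dec.sample_.w, mcfg
            )
            cis = contribution_intervals(draws, dec.sample_, X)
            log_lines.append(
                f"round {label}: Gibbs draws={mcfg.n_draws}, burn-in={mcfg.burn_in}, "
                f"seed={mcfg.seed}"
            )
        table3 = format_table3(result, cis)
        table3.to_csv(outdir / f"decomposition_{label}.csv", index_label="contributor")
        write_json(result.to_dict(), outdir / f"decomposition_{label}.json")
        manifest[f"decomposition_{label}"] = str(outdir / f"decomposition_{label}.csv")
        decompositions[label] = result

    if len(tables) == 2:
        before, after = (decompositions[label] for label, _ in tables)
        chg = oaxaca_change(before, after, variant=config.oaxaca_variant)
        gap = chg.additivity_gap()
        if gap > _ADDITIVITY_TOL:
            raise AssertionError(f"change additivity violated (gap {gap:.3e})")
        log_lines.append(f"change: additivity gap {gap:.3e}")
        format_table4(chg).to_csv(outdir / "change_decomposition.csv", index_label="contributor")
        write_json(chg.to_dict(), outdir / "change_decomposition.json")
        manifest["change_decomposition"] = str(outdir / "change_decomposition.csv")

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest["run_log"] = str(outdir / "run.log")
    for line in log_lines:
        logger.info(line)
    return manifest
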
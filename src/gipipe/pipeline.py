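"""End-to-end orchestration: simulate/load -> classify -> score -> AGI ->
cross-tabulate -> associate -> survival, from a single (YAML-able) config.

Every stage's output is a CSV under the configured directory; a JSON manifest
recording stage order, seeds, outputs and per-reason exclusion counts is
always written, even when a stage fails. Outputs are a pure function of
(inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, scoring, stats, survival
from . import synthetic as _synthetic
from .classify import SignatureConfig, call_signature
from .data_io import DataError
from .synthetic import ADAPTIVE, IMMUNE_CLASSES, QUIET, SyntheticConfig

logger = logging.getLogger("gipipe")


# ---------------------------------------------------------------------------
# Cross-tabulation (Table-1-style counts + column percentages)
# ---------------------------------------------------------------------------


@dataclass
class CrossTab:
    """Counts and column percentages for one row-variable block.

    ``denominator`` records the policy used: ``"full"`` divides by the whole
    column including missing row values; ``"observed"`` divides by the
    non-missing rows only. The emulated study's summary table mixes both
    conventions across row blocks, so the policy is explicit, never implied.
    """

    counts: pd.DataFrame
    percents: pd.DataFrame
    denominator: str


def cross_tabulate(
    table: pd.DataFrame,
    row_var: str,
    col_var: str,
    *,
    denominator: str = "full",
) -> CrossTab:
    """Counts of ``row_var`` levels within each ``col_var`` column.

    Missing row values appear as a ``Missing`` row; percentages follow the
    declared denominator policy.
    """
    if denominator not in ("full", "observed"):
        raise DataError(f"denominator must be 'full' or 'observed', got {denominator!r}")
    if len(table) == 0:
        raise DataError("cross_tabulate: empty table")
    df = table[[row_var, col_var]].copy()
    df = df[df[col_var].notna()]
    rows = df[row_var].fillna("Missing")
    counts = pd.crosstab(rows, df[col_var])
    if "Missing" in counts.index:  # keep Missing last
        counts = counts.reindex(
            [r for r in counts.index if r != "Missing"] + ["Missing"]
        )
    if denominator == "full":
        denom = counts.sum(axis=0)
    else:
        observed = counts.drop(index="Missing", errors="ignore")
        denom = observed.sum(axis=0)
        counts = observed
    percents = 100.0 * counts / denom
    return CrossTab(counts=counts, percents=percents, denominator=denominator)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class InputPaths:
    expression: str
    annotations: str
    tp53_centroids: str
    hrd_centroids: str
    immune_centroids: str
    panel: str


@dataclass
class PipelineConfig:
    """Exactly one of ``inputs`` / ``simulate`` must be set."""

    out_dir: str
    inputs: InputPaths | None = None
    simulate: SyntheticConfig | None = None
    seed: int = 0
    run_crosstab: bool = True
    run_rfd: bool = True
    run_differential: bool = True
    run_summaries: bool = True
    run_survival: bool = True
    check_proportionality: bool = False
    rfd_covariates: tuple[str, ...] = ("age", "race")
    survival_covariates: tuple[str, ...] = ("age", "race", "stage", "er_status")
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise DataError("config must set exactly one of inputs / simulate")
        if self.inputs is not None:
            for f in dataclasses.fields(InputPaths):
                p = getattr(self.inputs, f.name)
                if not Path(p).exists():
                    raise DataError(f"input path does not exist: {f.name}={p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh)
        inputs = InputPaths(**raw["inputs"]) if raw.get("inputs") else None
        simulate = SyntheticConfig(**raw["simulate"]) if raw.get("simulate") is not None else None
        kwargs = {k: v for k, v in raw.items() if k not in ("inputs", "simulate")}
        for tup in ("rfd_covariates", "survival_covariates"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        return cls(inputs=inputs, simulate=simulate, **kwargs)


# ---------------------------------------------------------------------------
# Run
# ---------------------------------------------------------------------------


def run(config: PipelineConfig) -> dict:
    """Execute every enabled stage; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    manifest: dict = {
        "stages": [],
        "seed": config.seed,
        "outputs": [],
        "exclusions": {},
        "error": None,
    }

    def _record(stage: str, *paths: Path):
        manifest["stages"].append(stage)
        manifest["outputs"].extend(str(p) for p in paths)

    try:
        # ---- stage: acquire data ----
        if config.simulate is not None:
            sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
            cohort = _synthetic.generate_cohort(sim_cfg)
            expr, annotations = cohort.expression, cohort.annotations
            centroids = _synthetic.true_centroids(sim_cfg)
            panel = _synthetic.default_marker_panel()
            data_io.write_expression(expr, out / "expression.tsv")
            data_io.write_annotations(annotations, out / "annotations.csv")
            cohort.truth.to_csv(out / "truth.csv", index=False)
            _record("simulate", out / "expression.tsv", out / "annotations.csv",
                    out / "truth.csv")
        else:
            expr = data_io.read_expression(config.inputs.expression)
            annotations = data_io.read_annotations(config.inputs.annotations)
            centroids = {
                "tp53": data_io.read_centroids(config.inputs.tp53_centroids),
                "hrd": data_io.read_centroids(config.inputs.hrd_centroids),
                "immune": data_io.read_centroids(config.inputs.immune_centroids),
            }
            panel = data_io.read_panel(config.inputs.panel)
            _record("load")
        annotations = annotations.set_index("sample_id", drop=False)

        # ---- stage: classification ----
        sigs = {
            "tp53": SignatureConfig(centroids["tp53"],
                                              ["Mut-like", "WT-like"]),
            "hrd": SignatureConfig(centroids["hrd"], ["HRD+", "HRD-"]),
            "immune": SignatureConfig(centroids["immune"],
                                                list(IMMUNE_CLASSES)),
        }
        calls = {}
        for name, sig in sigs.items():
            calls[name] = call_signature(expr, sig)
            calls[name].to_csv(out / f"calls_{name}.csv")
        _record("classify", *[out / f"calls_{n}.csv" for n in sigs])

        # ---- stage: scores + AGI ----
        score_table = scoring.compute_scores(expr, panel)
        for single in ("PD-L1", "CD8"):
            if single in score_table:
                score_table[f"{single} class"] = scoring.dichotomize_q3(
                    score_table[single]
                )
        score_table.to_csv(out / "scores.csv")
        agi = scoring.call_agi(
            calls["tp53"]["label"].replace("missing", np.nan),
            calls["hrd"]["label"].replace("missing", np.nan),
        )
        agi.to_csv(out / "agi.csv")
        _record("score", out / "scores.csv", out / "agi.csv")

        merged = annotations.join(agi[["tp53", "hrd", "agi"]]).join(
            calls["immune"]["label"].rename("immune_class")
        ).join(score_table)

        # ---- stage: cross-tabulation ----
        if config.run_crosstab:
            blocks = []
            for row_var, denom in (("tp53", "full"), ("hrd", "observed"),
                                   ("agi", "observed"), ("immune_class", "full"),
                                   ("PD-L1 class", "full"), ("CD8 class", "full")):
                if row_var not in merged:
                    continue
                block = merged.copy()
                if row_var in ("tp53", "hrd"):
                    block[row_var] = block[row_var].replace("missing", np.nan)
                if row_var == "agi":
                    block[row_var] = block[row_var].replace("indeterminate", np.nan)
                ct = cross_tabulate(block, row_var, "er_status", denominator=denom)
                tidy = ct.counts.stack().rename("n").to_frame()
                tidy["percent"] = ct.percents.stack().round(1)
                tidy["denominator"] = ct.denominator
                tidy["variable"] = row_var
                blocks.append(tidy.reset_index().rename(columns={row_var: "level"}))
            pd.concat(blocks, ignore_index=True).to_csv(
                out / "crosstab.csv", index=False
            )
            _record("crosstab", out / "crosstab.csv")

        # ---- stage: RFD associations (immune class outcome vs instability) ----
        if config.run_rfd:
            covs = merged[list(config.rfd_covariates)]
            rfd_rows = []
            for exposure, index_level, referent in (
                ("tp53", "Mut-like", "WT-like"),
                ("hrd", "HRD+", "HRD-"),
                ("PD-L1 class", "High", "Low"),
            ):
                if exposure not in merged:
                    continue
                expo = merged[exposure].replace(
                    {"missing": np.nan, "indeterminate": np.nan}
                )
                for cls in (c for c in IMMUNE_CLASSES if c != QUIET):
                    in_pair = merged["immune_class"].isin([cls, QUIET])
                    outcome = (merged.loc[in_pair, "immune_class"] == cls).astype(float)
                    for res in stats.estimate_rfd(
                        outcome,
                        expo[in_pair],
                        covariates=covs[in_pair],
                        referent=referent,
                        outcome_name=f"{cls} vs {QUIET}",
                    ):
                        rfd_rows.append(dataclasses.asdict(res))
            pd.DataFrame(rfd_rows).to_csv(out / "rfd.csv", index=False)
            _record("rfd", out / "rfd.csv")

        # ---- stage: differential immune scores ----
        if config.run_differential:
            score_cols = [c for c in score_table.columns
                          if not c.endswith(" class")]
            diff_frames = []
            for contrast, index_level in (("tp53", "Mut-like"), ("hrd", "HRD+")):
                grp = merged[contrast].replace("missing", np.nan)
                keep = grp.notna()
                res = stats.differential_scores(
                    merged.loc[keep, score_cols],
                    (grp[keep] == index_level).astype(int),
                    covariates=merged.loc[keep, list(config.rfd_covariates)],
                )
                res["contrast"] = contrast
                diff_frames.append(res.reset_index())
            pd.concat(diff_frames, ignore_index=True).to_csv(
                out / "differential_scores.csv", index=False
            )
            _record("differential", out / "differential_scores.csv")

        # ---- stage: overall-immune summaries (Welch by AGI within ER) ----
        if config.run_summaries:
            oi = score_table["overall-immune"]
            rows = []
            for er in ("positive", "negative"):
                sub = merged[merged["er_status"] == er]
                a = oi[sub.index[sub["agi"] == "AGI"]]
                ngi = oi[sub.index[sub["agi"] == "NGI"]]
                if a.notna().sum() >= 2 and ngi.notna().sum() >= 2:
                    w = stats.welch_t(a, ngi)
                    rows.append({"er_status": er, "mean_agi": a.mean(),
                                 "mean_ngi": ngi.mean(), "t": w.t, "df": w.df,
                                 "p": w.p})
            pd.DataFrame(rows).to_csv(out / "overall_immune.csv", index=False)
            _record("summaries", out / "overall_immune.csv")

        # ---- stage: AGI-stratified recurrence analysis ----
        if config.run_survival:
            reports, exclusions = survival.recurrence_analysis(
                merged.reset_index(drop=True),
                referent_class=ADAPTIVE,
                adjust=tuple(config.survival_covariates),
                check_proportionality=config.check_proportionality,
            )
            manifest["exclusions"]["survival"] = exclusions
            logrank_rows = []
            for stratum, rep in reports.items():
                for cls, curve in rep.km.curves.items():
                    curve.assign(immune_class=cls).to_csv(
                        out / f"km_{stratum}_{cls}.csv", index=False
                    )
                if rep.cox_rows is not None:
                    rep.cox_rows.to_csv(out / f"cox_{stratum}.csv")
                logrank_rows.append(
                    {"stratum": stratum, "chi2": rep.km.logrank_chi2,
                     "p": rep.km.logrank_p, "df": rep.km.df,
                     "skipped": rep.km.skipped_reason}
                )
            pd.DataFrame(logrank_rows).to_csv(out / "logrank.csv", index=False)
            _record("survival", out / "logrank.csv")
    except Exception as exc:  # manifest is always written, even on failure
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with (out / "manifest.json").open("w") as fh:
            json.dump(manifest, fh, indent=1)
        raise
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
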
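"""End-to-end orchestration: clean, filter, fit both models, report.

The full analysis mirrors the census protocol: pedigree cleaning
(founderize adoptees, remove loops, truncate above grandparents, prune
non-informative branches), score filtering (range, earliest-score
deduplication, adoptee / no-parentage exclusion), then two mixed-model fits —
an intercept-only "empty" model on all eligible children and a covariate
"full" model on the subset with a defined SES weight — followed by posterior
summaries and the share of variance explained by the covariates.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import phenotypes as ph
from .errors import ValidationError
from .model import (
    MCMCConfig,
    ModelSpec,
    PosteriorSummary,
    explained_by_covariates,
    gibbs_fit,
    summarize,
)
from .pedigree import (
    Pedigree,
    build_relationship_structure,
    clean_pedigree,
    read_pedigree,
)
from .simulate import SimConfig, preset, simulate_dataset, write_fixture

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and knobs for one end-to-end run.

    Exactly one of (``pedigree_path``/``scores_path``/``covariates_path``) or
    ``sim`` must be provided.
    """

    pedigree_path: str | None = None
    scores_path: str | None = None
    covariates_path: str | None = None
    sim: SimConfig | None = None
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    empty_only: bool = False
    truncate_depth: int = 2
    out_dir: str | None = None
    report_format: str = "text"  # text | csv | json

    def __post_init__(self) -> None:
        has_paths = any(
            p is not None
            for p in (self.pedigree_path, self.scores_path, self.covariates_path)
        )
        if has_paths == (self.sim is not None):
            raise ValidationError(
                "provide either input paths or a simulation config, not both"
            )


@dataclass
class RunReport:
    filter_report: ph.FilterReport
    cleaning_counts: dict[str, int]
    n_empty: int
    n_full: int | None
    empty_summary: PosteriorSummary
    full_summary: PosteriorSummary | None
    explained_points: float | None
    explained_percent: float | None
    config_fingerprint: dict


def _set_phenotyped(ped: Pedigree, ids: set[str]) -> Pedigree:
    return Pedigree(
        {
            i.id: (replace(i, phenotyped=i.id in ids) if i.phenotyped != (i.id in ids) else i)
            for i in ped
        }
    )


def _fit(ped: Pedigree, scores, covariates, ids, include_covariates, mcmc, mode):
    ped_m = _set_phenotyped(ped, set(ids))
    rel = build_relationship_structure(ped_m)
    design = ph.build_design_matrix(
        scores, covariates, include_covariates=include_covariates, ids=ids
    )
    spec = ModelSpec(design=design, relationship=rel, mode=mode)
    return gibbs_fit(spec, mcmc)


def run_analysis(config: RunConfig) -> RunReport:
    """Execute the whole pipeline and return the consolidated report.

    Deterministic given the config: the same seeds reproduce the same
    cleaned data, draws and summaries exactly.
    """
    if config.sim is not None:
        sim = simulate_dataset(config.sim)
        ped_raw, scores_raw, covariates = sim.pedigree, sim.scores, sim.covariates
        if config.out_dir:
            write_fixture(sim, Path(config.out_dir) / "fixture")
    else:
        scores_raw = ph.read_scores(config.scores_path)
        covariates = (
            ph.read_covariates(config.covariates_path)
            if config.covariates_path
            else None
        )
        ped_raw = read_pedigree(config.pedigree_path)

    # phenotype filters define who counts as phenotyped during cleaning
    scores, rep_range = ph.filter_score_range(scores_raw)
    scores, rep_dedup = ph.dedup_earliest(scores)
    ped_flagged = _set_phenotyped(ped_raw, set(scores["child_id"]))
    ped, cleaning = clean_pedigree(ped_flagged, depth=config.truncate_depth)

    ids_empty, rep_excl = ph.exclude_rows(
        scores, covariates, ped, drop_adopted=True, drop_no_parentage=True
    )
    report = ph.FilterReport.combine(rep_range, rep_dedup, rep_excl)

    mcmc_full = dataclasses.replace(config.mcmc, seed=config.mcmc.seed + 1)
    draws_empty = _fit(ped, scores, None, ids_empty, False, config.mcmc, "empty")
    empty_summary = summarize(draws_empty)

    full_summary = None
    n_full = None
    explained_pts = explained_pct = None
    draws_full = None
    if not config.empty_only:
        if covariates is None:
            raise ValidationError("full model requested but no covariates given")
        sub = scores[scores["child_id"].isin(set(ids_empty))]
        ids_full, rep_spec = ph.exclude_rows(
            sub, covariates, ped, drop_adopted=False,
            drop_no_parentage=False, drop_special_ed=True,
        )
        report = ph.FilterReport.combine(report, rep_spec)
        n_full = len(ids_full)
        draws_full = _fit(ped, scores, covariates, ids_full, True, mcmc_full, "full")
        full_summary = summarize(draws_full)
        explained_pts, explained_pct = explained_by_covariates(
            empty_summary, full_summary
        )

    out = RunReport(
        filter_report=report,
        cleaning_counts=cleaning,
        n_empty=len(ids_empty),
        n_full=n_full,
        empty_summary=empty_summary,
        full_summary=full_summary,
        explained_points=explained_pts,
        explained_percent=explained_pct,
        config_fingerprint=_fingerprint(config),
    )
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        draws_empty.to_frame().to_csv(out_dir / "draws_empty.csv", index=False)
        if draws_full is not None:
            draws_full.to_frame().to_csv(out_dir / "draws_full.csv", index=False)
        render_tables(out, config.report_format, out_dir)
    return out


def _fingerprint(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        return obj

    return {"pedherit": _version(), "config": enc(config)}


def _version() -> str:
    from . import __version__

    return __version__


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _vc_rows(report: RunReport) -> list[dict]:
    rows = []
    for label, s in [("empty", report.empty_summary), ("full", report.full_summary)]:
        if s is None:
            continue
        rows.append(
            {
                "model": label,
                "sigma2_A_mean": s.mean("sigma2_A"),
                "sigma2_A_sd": s.sd("sigma2_A"),
                "sigma2_E_mean": s.mean("sigma2_E"),
                "sigma2_E_sd": s.sd("sigma2_E"),
                "h2_mean": s.mean("h2"),
                "h2_sd": s.sd("h2"),
            }
        )
    return rows


def _coef_rows(report: RunReport) -> list[dict]:
    if report.full_summary is None:
        return []
    rows = []
    s = report.full_summary
    order = [k for k in s.params if k == "mu" or k.startswith("beta_")]
    for key in order:
        name = "Intercept" if key == "mu" else key.removeprefix("beta_")
        mean, sd = s.params[key]
        rows.append({"coefficient": name, "posterior_mean": mean, "posterior_sd": sd})
        if name == "migrant_1":
            rows.insert(-1, {"coefficient": "migrant_0", "posterior_mean": 0.0,
                             "posterior_sd": None})
        if name.startswith("denom_") and not any(
            r["coefficient"] == "denom_ABZ" for r in rows
        ):
            rows.insert(-1, {"coefficient": "denom_ABZ", "posterior_mean": 0.0,
                             "posterior_sd": None})
    return rows


def render_tables(report: RunReport, fmt: str, out_dir: str | Path) -> list[Path]:
    """Emit the variance-components/heritability table and (for the full
    model) the coefficient table, with reference categories shown as 0."""
    if fmt not in {"text", "csv", "json"}:
        raise ValidationError(f"unknown report format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vc, coef = _vc_rows(report), _coef_rows(report)
    written: list[Path] = []

    if fmt == "json":
        p = out_dir / "report.json"
        p.write_text(
            json.dumps(
                {
                    "variance_components": vc,
                    "coefficients": coef,
                    "n_empty": report.n_empty,
                    "n_full": report.n_full,
                    "explained_points": report.explained_points,
                    "explained_percent": report.explained_percent,
                    "filter_report": dataclasses.asdict(report.filter_report),
                    "cleaning_counts": report.cleaning_counts,
                },
                indent=2,
            )
            + "\n"
        )
        written.append(p)
    elif fmt == "csv":
        p1 = out_dir / "variance_components.csv"
        pd.DataFrame(vc).to_csv(p1, index=False)
        written.append(p1)
        if coef:
            p2 = out_dir / "coefficients.csv"
            pd.DataFrame(coef).to_csv(p2, index=False)
            written.append(p2)
    else:
        lines = ["Posterior means (and SDs) for variance components and heritability", ""]
        lines.append(f"{'model':<8}{'sigma2_A':>18}{'sigma2_E':>18}{'h2':>18}")
        for r in vc:
            lines.append(
                f"{r['model']:<8}"
                f"{r['sigma2_A_mean']:>10.2f} ({r['sigma2_A_sd']:.2f})"
                f"{r['sigma2_E_mean']:>10.2f} ({r['sigma2_E_sd']:.2f})"
                f"{r['h2_mean']:>10.3f} ({r['h2_sd']:.3f})"
            )
        lines.append("")
        lines.append(f"N (empty model) = {report.n_empty}")
        if report.n_full is not None:
            lines.append(f"N (full model)  = {report.n_full}")
        if report.explained_points is not None:
            lines.append(
                f"variance explained by covariates: {report.explained_points:.2f} "
                f"points ({report.explained_percent:.1f}%)"
            )
        if coef:
            lines += ["", "Regression coefficients (full model)", ""]
            lines.append(f"{'coefficient':<16}{'mean':>10}{'sd':>10}")
            for r in coef:
                sd = "-" if r["posterior_sd"] is None else f"{r['posterior_sd']:.3f}"
                lines.append(
                    f"{r['coefficient']:<16}{r['posterior_mean']:>10.3f}{sd:>10}"
                )
        p = out_dir / "report.txt"
        p.write_text("\n".join(lines) + "\n")
        written.append(p)
    return written
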
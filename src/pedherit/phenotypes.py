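"""Phenotype filtering, deduplication, and covariate design matrices.

The phenotype is a standardized end-of-primary-school test score on a 500-550
point scale. Filtering follows the census analysis protocol: keep only scores
inside the valid range, keep each child's earliest score when several years
are present, and exclude adoptees, children without parentage records, and
(for the covariate model only) special-education pupils whose SES weight is
undefined. Covariates are reference-coded: Female, migrant status 0, and
school denomination ABZ carry no design column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .errors import ValidationError
from .pedigree import Pedigree

log = logging.getLogger(__name__)

SCORE_COLUMNS = ["child_id", "year", "score"]
COVARIATE_COLUMNS = [
    "child_id",
    "sex",
    "weight",
    "group_size",
    "migrant_status",
    "denomination",
    "special_education",
]


@dataclass
class FilterReport:
    """Record-count bookkeeping across the filtering stages.

    ``n_final + (all exclusion counts) == n_input`` for each stage's report;
    :meth:`combine` sums stage reports into one pipeline-level account.
    """

    n_input: int = 0
    n_out_of_range: int = 0
    n_duplicates_resolved: int = 0
    n_adopted_excluded: int = 0
    n_no_parentage: int = 0
    n_special_ed_excluded: int = 0
    n_final: int = 0

    def check(self) -> None:
        removed = (
            self.n_out_of_range
            + self.n_duplicates_resolved
            + self.n_adopted_excluded
            + self.n_no_parentage
            + self.n_special_ed_excluded
        )
        if self.n_input - removed != self.n_final:
            raise ValidationError(f"filter counts do not reconcile: {self}")

    @staticmethod
    def combine(first: "FilterReport", *rest: "FilterReport") -> "FilterReport":
        out = FilterReport(**asdict(first))
        for r in rest:
            out.n_out_of_range += r.n_out_of_range
            out.n_duplicates_resolved += r.n_duplicates_resolved
            out.n_adopted_excluded += r.n_adopted_excluded
            out.n_no_parentage += r.n_no_parentage
            out.n_special_ed_excluded += r.n_special_ed_excluded
            out.n_final = r.n_final
        out.check()
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"child_id": str})
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing score columns {sorted(missing)}")
    return df[SCORE_COLUMNS]


def read_covariates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"child_id": str, "denomination": str})
    missing = set(COVARIATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing covariate columns {sorted(missing)}")
    df["special_education"] = df["special_education"].astype(bool)
    return df[COVARIATE_COLUMNS]


def filter_score_range(
    scores: pd.DataFrame,
    lo: float = constants.SCORE_MIN,
    hi: float = constants.SCORE_MAX,
) -> tuple[pd.DataFrame, FilterReport]:
    """Keep scores with ``lo <= score <= hi`` (inclusive: both endpoints are
    valid scale values). Non-numeric scores are dropped and counted with the
    out-of-range records."""
    rep = FilterReport(n_input=len(scores))
    numeric = pd.to_numeric(scores["score"], errors="coerce")
    n_bad = int(numeric.isna().sum())
    if n_bad:
        log.warning("filter_score_range: %d non-numeric scores dropped", n_bad)
    keep = numeric.between(lo, hi)
    out = scores.loc[keep.fillna(False)].copy()
    out["score"] = numeric[keep.fillna(False)]
    rep.n_out_of_range = rep.n_input - len(out)
    rep.n_final = len(out)
    rep.check()
    log.info("filter_score_range: removed %d of %d records", rep.n_out_of_range, rep.n_input)
    return out.reset_index(drop=True), rep


def dedup_earliest(scores: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Keep one score per child: the earliest year wins; a same-year tie is
    broken deterministically by the lower score (logged)."""
    rep = FilterReport(n_input=len(scores))
    n_ties = int(scores.duplicated(subset=["child_id", "year"]).sum())
    if n_ties:
        log.warning("dedup_earliest: %d same-year duplicates, keeping lower score", n_ties)
    out = (
        scores.sort_values(["child_id", "year", "score"], kind="mergesort")
        .drop_duplicates(subset="child_id", keep="first")
        .reset_index(drop=True)
    )
    rep.n_duplicates_resolved = rep.n_input - len(out)
    rep.n_final = len(out)
    rep.check()
    log.info("dedup_earliest: resolved %d duplicate records", rep.n_duplicates_resolved)
    return out, rep


def exclude_rows(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None,
    ped: Pedigree | None,
    drop_adopted: bool = True,
    drop_no_parentage: bool = True,
    drop_special_ed: bool = False,
) -> tuple[list[str], FilterReport]:
    """Return the analysis ID set after the requested exclusions.

    Adoptees and children without any parentage record are dropped for both
    models; the special-education exclusion applies only when the covariate
    (full) model is requested, since those pupils have no SES weight.
    """
    rep = FilterReport(n_input=len(scores))
    ids = scores["child_id"]
    keep = pd.Series(True, index=scores.index)

    if drop_adopted and ped is not None:
        adopted = ids.map(lambda i: i in ped and ped[i].adopted)
        rep.n_adopted_excluded = int((keep & adopted).sum())
        keep &= ~adopted
    if drop_no_parentage and ped is not None:
        has_parents = ids.map(lambda i: i in ped and bool(ped[i].known_parents()))
        rep.n_no_parentage = int((keep & ~has_parents).sum())
        keep &= has_parents
    if drop_special_ed:
        if covariates is None:
            raise ValidationError("special-education exclusion needs covariates")
        spec_ids = set(
            covariates.loc[covariates["special_education"], "child_id"]
        )
        is_spec = ids.isin(spec_ids)
        rep.n_special_ed_excluded = int((keep & is_spec).sum())
        keep &= ~is_spec

    final = ids[keep].tolist()
    if not final:
        log.warning("exclude_rows: no records remain after exclusions")
    rep.n_final = len(final)
    rep.check()
    return final, rep


@dataclass
class DesignMatrix:
    """Response vector and reference-coded predictor matrix.

    ``row_ids`` are sorted child IDs, matching the ID order of the
    relationship structure built from the same pedigree.
    """

    response: np.ndarray
    X: np.ndarray
    columns: list[str]
    row_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.row_ids)


def build_design_matrix(
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    include_covariates: bool = False,
    ids: list[str] | None = None,
) -> DesignMatrix:
    """Assemble the response and design matrix for the mixed model.

    With ``include_covariates=False`` the design is intercept-only (the empty
    model). Otherwise the columns are: intercept, Male indicator, SES weight
    (continuous), group size (continuous), migrant-status 1 and 2 indicators,
    and one indicator per non-reference school denomination present in the
    data, ordered alphabetically.
    """
    df = scores if ids is None else scores[scores["child_id"].isin(set(ids))]
    df = df.sort_values("child_id", kind="mergesort").reset_index(drop=True)
    row_ids = df["child_id"].tolist()
    y = df["score"].to_numpy(dtype=float)
    n = len(df)
    if not include_covariates:
        return DesignMatrix(y, np.ones((n, 1)), ["intercept"], row_ids)

    if covariates is None:
        raise ValidationError("covariates required for the full model")
    cov = covariates.set_index("child_id").reindex(row_ids)
    if cov["sex"].isna().any():
        bad = [row_ids[k] for k in np.flatnonzero(cov["sex"].isna().to_numpy())][:5]
        raise ValidationError(f"missing covariate rows for children {bad}")
    w = pd.to_numeric(cov["weight"], errors="coerce")
    if w.isna().any():
        bad = [row_ids[k] for k in np.flatnonzero(w.isna().to_numpy())][:5]
        raise ValidationError(
            f"missing SES weight for children {bad}; exclude special education first"
        )

    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    cols.append((cov["sex"].to_numpy() == "Male").astype(float))
    names.append("Male")
    cols.append(w.to_numpy(dtype=float))
    names.append("weight")
    cols.append(pd.to_numeric(cov["group_size"]).to_numpy(dtype=float))
    names.append("group_size")
    mig = pd.to_numeric(cov["migrant_status"]).to_numpy()
    for level in (1, 2):
        cols.append((mig == level).astype(float))
        names.append(f"migrant_{level}")
    denoms = sorted(set(cov["denomination"]) - {constants.REFERENCE_DENOMINATION})
    unseen = [d for d in denoms if d not in constants.DENOMINATION_FREQS]
    if unseen:
        log.warning("build_design_matrix: unseen denomination codes %s", unseen)
    for d in denoms:
        cols.append((cov["denomination"].to_numpy() == d).astype(float))
        names.append(f"denom_{d}")
    return DesignMatrix(y, np.column_stack(cols), names, row_ids)


def summarize_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Frequency table (count, percent) per categorical covariate, in the
    layout of the published covariate overview."""
    rows = []
    for var in ["sex", "weight", "migrant_status", "denomination"]:
        counts = covariates[var].value_counts(dropna=False).sort_index()
        total = counts.sum()
        for level, n in counts.items():
            rows.append(
                {
                    "variable": var,
                    "category": level,
                    "n": int(n),
                    "percent": round(100.0 * n / total, 2) if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["variable", "category", "n", "percent"])
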
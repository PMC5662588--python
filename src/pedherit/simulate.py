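"""Synthetic census generator with known ground truth.

Emulates a multi-generation national register: founder couples have
Poisson-distributed numbers of children, children partner within their
generation (creating full- and half-cousin links in the next one) or with
immigrant founders, parents re-partner at a configurable rate (creating half
siblings), and monozygotic twin pairs occur at roughly one per 200 births.
The youngest generation is phenotyped.

Breeding values follow the additive infinitesimal model by Mendelian
sampling: founders draw N(0, sigma2_A); a child receives the mean of its
parents' values plus a Mendelian deviation of variance sigma2_A / 2, with an
unknown parent's contribution replaced by extra deviation variance
(sigma2_A / 4 per unknown parent) so every individual's marginal variance is
sigma2_A. MZ co-twins share one value. Phenotypes add covariate effects and
independent residuals; optional corruption (adoptions, parentage loops,
duplicate and out-of-range scores) exercises the cleaning and filter stages,
with exact bookkeeping of what was injected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants
from .errors import ValidationError
from .pedigree import Individual, Pedigree, _topological_ids, write_pedigree

log = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Generative parameters for the synthetic census.

    Defaults reproduce the published study conditions: empty-model variance
    components, mean score 535.03, MZ twinning at 1/200 births, covariates at
    the national category frequencies with the reported effect sizes.
    """

    n_families: int = 200  # founder couples
    mean_children: float = 2.4  # Poisson mean per couple
    generations: int = 3  # >= 3 so cousins arise
    twin_rate: float = constants.MZ_TWIN_RATE  # MZ pair probability per birth
    repartner_rate: float = 0.10  # second partner probability per couple
    # chance an individual partners outside the simulated clans; above ~0.6 the
    # sibship-marriage graph is subcritical, keeping extended families bounded
    immigrant_rate: float = 0.70
    sigma2_A: float = constants.EMPTY_MODEL_VC["sigma2_A"]
    sigma2_E: float = constants.EMPTY_MODEL_VC["sigma2_E"]
    mean: float = constants.MEAN_SCORE
    with_covariate_effects: bool = False  # apply the reported regression effects
    round_scores: bool = False
    clamp_scores: bool = False  # clip to the 500-550 scale (off: keeps the
    # generating model identical to the fitted one)
    # corruption rates / counts, all with exact bookkeeping in GroundTruth
    adoption_rate: float = 0.0
    n_loops: int = 0
    duplicate_rate: float = 0.0
    out_of_range_rate: float = 0.0
    special_ed_rate: float = constants.SPECIAL_ED_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("twin_rate", "repartner_rate", "immigrant_rate",
                     "adoption_rate", "duplicate_rate", "out_of_range_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.generations < 2:
            raise ValidationError("need at least 2 generations")

    @property
    def h2(self) -> float:
        return self.sigma2_A / (self.sigma2_A + self.sigma2_E)


@dataclass
class GroundTruth:
    """What the generator knows and the estimators must recover."""

    h2: float
    sigma2_A: float
    sigma2_E: float
    mean: float
    breeding_values: dict[str, float] = field(default_factory=dict)
    mz_pairs: list[tuple[str, str]] = field(default_factory=list)
    adoptees: list[str] = field(default_factory=list)
    loop_members: list[str] = field(default_factory=list)
    n_duplicates: int = 0
    n_out_of_range: int = 0
    n_special_ed: int = 0

    def co_twin(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for a, b in self.mz_pairs:
            out[a] = b
            out[b] = a
        return out


PRESETS = {
    "tiny": dict(n_families=42, seed=0),  # ~200 phenotyped children
    "desk": dict(n_families=920, seed=0),  # ~5,000 phenotyped children
    "stress": dict(n_families=18400, seed=0),  # ~100,000 phenotyped children
}


def preset(name: str, **overrides) -> SimConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# pedigree structure
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> tuple[Pedigree, GroundTruth]:
    """Build the multi-generation pedigree; the final generation is phenotyped.

    Partnering avoids pairs that share a parent or grandparent, so the
    pedigree stays non-inbred at the depth the analysis retains. Corruption
    (adoption flags, parentage loops) is injected last, with the affected IDs
    recorded in the returned ground truth.
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(
        h2=config.h2, sigma2_A=config.sigma2_A,
        sigma2_E=config.sigma2_E, mean=config.mean,
    )
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:07d}"

    inds: dict[str, Individual] = {}

    def add(father=None, mother=None) -> str:
        iid = new_id()
        inds[iid] = Individual(id=iid, father=father, mother=mother)
        return iid

    # founder couples
    couples = [(add(), add()) for _ in range(config.n_families)]

    generation: list[str] = []
    for gen in range(1, config.generations):
        generation = []
        for father, mother in couples:
            n_births = rng.poisson(config.mean_children)
            for _ in range(n_births):
                child = add(father, mother)
                generation.append(child)
                if rng.random() < config.twin_rate:
                    twin = add(father, mother)
                    generation.append(twin)
                    truth.mz_pairs.append((child, twin))
            # re-partnering: extra children with a second (immigrant) partner
            if rng.random() < config.repartner_rate:
                partner = add()
                for _ in range(rng.poisson(config.mean_children * 0.6)):
                    child = add(father, partner)
                    generation.append(child)
        if gen == config.generations - 1:
            break
        couples = _pair_generation(generation, inds, config, rng, add)

    if not generation:
        raise ValidationError("configuration produced no phenotyped individuals")
    for iid in generation:
        inds[iid] = replace(inds[iid], phenotyped=True)

    _inject_adoptions(inds, truth, config, rng)
    _inject_loops(inds, truth, config, rng, add)
    log.info(
        "simulate_pedigree: %d individuals, %d phenotyped, %d MZ pairs",
        len(inds), len(generation), len(truth.mz_pairs),
    )
    return Pedigree(inds), truth


def _grandparental_ancestry(inds: dict[str, Individual], iid: str) -> set[str]:
    out: set[str] = set()
    ind = inds[iid]
    for p in ind.known_parents():
        out.add(p)
        out.update(inds[p].known_parents())
    return out


def _pair_generation(pool, inds, config, rng, add):
    """Partner a generation into couples: within-pool (avoiding relatives up
    to shared grandparents) or with fresh immigrant founders."""
    pool = list(pool)
    rng.shuffle(pool)
    couples = []
    singles = []
    for iid in pool:
        if rng.random() < config.immigrant_rate:
            couples.append((iid, add()))
        else:
            singles.append(iid)
    unmatched: list[str] = []
    while singles:
        a = singles.pop()
        anc_a = _grandparental_ancestry(inds, a)
        partner = None
        for k, b in enumerate(singles):
            if not (anc_a & _grandparental_ancestry(inds, b)):
                partner = singles.pop(k)
                break
        if partner is None:
            unmatched.append(a)
        else:
            couples.append((a, partner))
    for a in unmatched:
        couples.append((a, add()))
    return couples


def _inject_adoptions(inds, truth, config, rng) -> None:
    if config.adoption_rate <= 0:
        return
    with_parents = [i for i, ind in inds.items() if ind.known_parents()]
    n = int(round(config.adoption_rate * len(with_parents)))
    for iid in rng.choice(with_parents, size=min(n, len(with_parents)), replace=False):
        inds[iid] = replace(inds[iid], adopted=True)
        truth.adoptees.append(iid)
    truth.adoptees.sort()


def _inject_loops(inds, truth, config, rng, add) -> None:
    """Add small parentage cycles among fresh non-phenotyped individuals so
    the injected cycle membership is known exactly."""
    for _ in range(config.n_loops):
        size = int(rng.integers(2, 4))
        members = [add() for _ in range(size)]
        for k, iid in enumerate(members):
            parent = members[(k + 1) % size]
            inds[iid] = replace(inds[iid], father=parent)
        truth.loop_members.extend(members)
    truth.loop_members.sort()


# ---------------------------------------------------------------------------
# breeding values and phenotypes
# ---------------------------------------------------------------------------


def simulate_breeding_values(
    ped: Pedigree,
    sigma2_A: float,
    seed: int,
    mz_pairs: list[tuple[str, str]] | None = None,
) -> dict[str, float]:
    """Mendelian-sampling breeding values over an acyclic pedigree.

    a_i = (a_father + a_mother) / 2 + m_i with Var(m_i) = sigma2_A / 2, plus
    sigma2_A / 4 per unknown parent, so marginal Var(a_i) = sigma2_A for all
    individuals. MZ co-twins copy one draw.
    """
    rng = np.random.default_rng(seed)
    co_twin = {}
    for a, b in mz_pairs or []:
        co_twin[b] = a  # second-born copies the first
    sd = np.sqrt(sigma2_A)
    values: dict[str, float] = {}
    for iid in _topological_ids(ped):
        if iid in co_twin and co_twin[iid] in values:
            values[iid] = values[co_twin[iid]]
            continue
        ind = ped[iid]
        known = [p for p in ind.known_parents() if p in ped]
        if sigma2_A == 0.0:
            values[iid] = 0.0
            continue
        mid = sum(values[p] for p in known) / 2.0
        mend_var = 0.5 + 0.25 * (2 - len(known))
        values[iid] = mid + rng.standard_normal() * sd * np.sqrt(mend_var)
    return values


def simulate_phenotypes(
    ped: Pedigree,
    breeding_values: dict[str, float],
    config: SimConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scores and covariates for the phenotyped individuals.

    y_i = mean + x_i' beta + a_i + e_i with e_i ~ N(0, sigma2_E). Covariates
    are sampled independently at the national category frequencies; their
    effects are applied only when ``with_covariate_effects`` is set.
    Duplicate-year and out-of-range corruption is applied last, with counts
    recorded on ``truth``.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    ids = ped.phenotyped_ids()
    n = len(ids)

    sexes = np.array(list(constants.SEX_FREQS))
    sex = rng.choice(sexes, size=n, p=_norm(constants.SEX_FREQS.values()))
    wvals = np.array(list(constants.WEIGHT_FREQS))
    weight = rng.choice(wvals, size=n, p=_norm(constants.WEIGHT_FREQS.values()))
    group = np.round(
        rng.normal(constants.GROUP_SIZE_MEAN, constants.GROUP_SIZE_SD, size=n)
    ).clip(5, 45)
    mvals = np.array(list(constants.MIGRANT_FREQS))
    migrant = rng.choice(mvals, size=n, p=_norm(constants.MIGRANT_FREQS.values()))
    dvals = np.array(list(constants.DENOMINATION_FREQS))
    denom = rng.choice(dvals, size=n, p=_norm(constants.DENOMINATION_FREQS.values()))
    special = rng.random(n) < config.special_ed_rate

    effect = np.zeros(n)
    if config.with_covariate_effects:
        effect += constants.BETA_MALE * (sex == "Male")
        effect += constants.BETA_WEIGHT * weight
        effect += constants.BETA_GROUP_SIZE * group
        for lvl, b in constants.BETA_MIGRANT.items():
            effect += b * (migrant == lvl)
        for code, b in constants.BETA_DENOMINATION.items():
            effect += b * (denom == code)

    a = np.array([breeding_values[i] for i in ids])
    e = rng.normal(0.0, np.sqrt(config.sigma2_E), size=n)
    y = config.mean + effect + a + e
    if config.clamp_scores:
        y = y.clip(constants.SCORE_MIN, constants.SCORE_MAX)
    if config.round_scores:
        y = np.round(y)

    year = rng.integers(2008, 2015, size=n)
    scores = pd.DataFrame({"child_id": ids, "year": year, "score": y})
    cov = pd.DataFrame(
        {
            "child_id": ids,
            "sex": sex,
            "weight": weight,
            "group_size": group.astype(int),
            "migrant_status": migrant.astype(int),
            "denomination": denom,
            "special_education": special,
        }
    )
    cov.loc[special, "weight"] = np.nan

    n_dup = int(round(config.duplicate_rate * n))
    if n_dup:
        pick = rng.choice(n, size=n_dup, replace=False)
        extra = scores.iloc[pick].copy()
        extra["year"] = extra["year"] + rng.integers(1, 3, size=n_dup)
        extra["score"] = (extra["score"] + rng.normal(0, 1, size=n_dup)).to_numpy()
        scores = pd.concat([scores, extra], ignore_index=True)
    n_oor = int(round(config.out_of_range_rate * len(scores)))
    if n_oor:
        pick = rng.choice(len(scores), size=n_oor, replace=False)
        bad = rng.choice([499.0, 551.0, 0.0, 999.0], size=n_oor)
        scores.iloc[pick, scores.columns.get_loc("score")] = bad

    if truth is not None:
        truth.n_duplicates = n_dup
        # exact ledger: corrupted rows plus any natural Gaussian tail mass
        # falling outside the bounded score scale
        truth.n_out_of_range = int(
            (~scores["score"].between(constants.SCORE_MIN, constants.SCORE_MAX)).sum()
        )
        truth.n_special_ed = int(special.sum())
    scores = scores.sort_values(["child_id", "year"], kind="mergesort").reset_index(
        drop=True
    )
    return scores, cov


def _norm(vals) -> np.ndarray:
    v = np.fromiter(vals, dtype=float)
    return v / v.sum()


@dataclass
class SimResult:
    pedigree: Pedigree
    scores: pd.DataFrame
    covariates: pd.DataFrame
    truth: GroundTruth


def simulate_dataset(config: SimConfig) -> SimResult:
    """Full generator pipeline: pedigree, breeding values, phenotypes."""
    ped, truth = simulate_pedigree(config)
    # injected loop corruption has no genetic meaning: breeding values are
    # drawn on the acyclic part (loop members carry no phenotype)
    acyclic = ped
    if truth.loop_members:
        from .pedigree import remove_loops

        acyclic, _ = remove_loops(ped)
    truth.breeding_values = simulate_breeding_values(
        acyclic, config.sigma2_A, seed=config.seed + 1, mz_pairs=truth.mz_pairs
    )
    scores, cov = simulate_phenotypes(ped, truth.breeding_values, config, truth)
    return SimResult(ped, scores, cov, truth)


def write_fixture(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write pedigree.tsv, scores.csv, covariates.csv and truth.json in the
    dialects the readers accept; round-trips losslessly."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.tsv",
        "scores": out / "scores.csv",
        "covariates": out / "covariates.csv",
        "truth": out / "truth.json",
    }
    write_pedigree(result.pedigree, paths["pedigree"])
    result.scores.to_csv(paths["scores"], index=False)
    result.covariates.to_csv(paths["covariates"], index=False)
    t = result.truth
    payload = {
        "h2": t.h2,
        "sigma2_A": t.sigma2_A,
        "sigma2_E": t.sigma2_E,
        "mean": t.mean,
        "mz_pairs": t.mz_pairs,
        "adoptees": t.adoptees,
        "loop_members": t.loop_members,
        "n_duplicates": t.n_duplicates,
        "n_out_of_range": t.n_out_of_range,
        "n_special_ed": t.n_special_ed,
        "phenotyped_ids": result.pedigree.phenotyped_ids(),
        "breeding_values": t.breeding_values,
    }
    paths["truth"].write_text(json.dumps(payload) + "\n")
    return paths


def read_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        h2=d["h2"],
        sigma2_A=d["sigma2_A"],
        sigma2_E=d["sigma2_E"],
        mean=d["mean"],
        breeding_values=d["breeding_values"],
        mz_pairs=[tuple(p) for p in d["mz_pairs"]],
        adoptees=d["adoptees"],
        loop_members=d["loop_members"],
        n_duplicates=d["n_duplicates"],
        n_out_of_range=d["n_out_of_range"],
        n_special_ed=d["n_special_ed"],
    )
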
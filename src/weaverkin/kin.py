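"""Spatial kin structure and kin-directed building statistics.

These are the colony-level statistics tying genetic relatedness to where
birds live in the communal nest and where they build: the decline of
relatedness with inter-chamber distance, the mean relatedness to occupants
of the nearest quarter of the colony's chambers ("local relatedness"), and
the visit-weighted fraction of a builder's thatch-building that lands above
its own chamber neighbourhood.

Contrasts that in field analyses would carry colony random effects are run
here as colony-stratified permutation tests: the sampling unit is permuted
only within its colony, which conditions on colony structure the same way a
random intercept would.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .datamodel import ChamberMap, Individual, ObservationLog
from .permstats import (
    PermTestResult,
    _perm_pvalue,
    node_label_test,
    wilcoxon_signed_rank,
)
from .popgen import RelatednessMatrix

__all__ = [
    "chamber_distance_matrix",
    "primary_chambers",
    "nearest_quartile_chambers",
    "local_relatedness",
    "relatedness_distance_slope",
    "building_location_score",
    "quartile_building_test",
    "builder_local_relatedness_contrast",
    "colony_vs_population_relatedness",
]


def chamber_distance_matrix(cmap: ChamberMap) -> tuple[list[str], np.ndarray]:
    """Euclidean distances between all chambers of one colony."""
    ids = cmap.ids
    xy = cmap.coords()
    diff = xy[:, None, :] - xy[None, :, :]
    return ids, np.sqrt((diff**2).sum(axis=2))


def primary_chambers(obs: ObservationLog, colony_id: str) -> dict[str, str]:
    """Most-visited chamber per bird (ties broken by chamber id)."""
    entries = obs.for_colony(colony_id).entries
    counts = entries.groupby(["bird_id", "chamber_id"]).size().reset_index(name="n")
    out: dict[str, str] = {}
    for bird, grp in counts.groupby("bird_id"):
        grp = grp.sort_values(["n", "chamber_id"], ascending=[False, True])
        out[str(bird)] = str(grp["chamber_id"].iloc[0])
    return out


def nearest_quartile_chambers(
    chamber_ids: list[str], distances: np.ndarray, focal_chamber: str
) -> list[str]:
    """The ceil(0.25 * (C - 1)) chambers nearest a focal chamber.

    The focal chamber itself is excluded; distance ties are broken by
    chamber id so the set is deterministic.
    """
    if len(chamber_ids) < 2:
        raise ValueError("need at least 2 chambers to define a nearest quartile")
    f = chamber_ids.index(focal_chamber)
    others = [(distances[f, i], cid) for i, cid in enumerate(chamber_ids) if i != f]
    others.sort()
    q = math.ceil(0.25 * (len(chamber_ids) - 1))
    return [cid for _, cid in others[:q]]


def local_relatedness(
    focal: str,
    r_matrix: RelatednessMatrix,
    occupancy: dict[str, list[str]],
    quartile_set: list[str],
    sex_filter: str | None = None,
    individuals: dict[str, Individual] | None = None,
) -> float:
    """Mean relatedness of a focal bird to occupants of its chamber quartile.

    ``occupancy`` maps chamber id to the birds assigned to it.  Occupants
    are deduplicated, the focal bird is excluded, and an optional sex filter
    restricts neighbours to one sex.  NaN when the neighbourhood is empty.
    """
    neighbours: set[str] = set()
    for c in quartile_set:
        neighbours.update(occupancy.get(c, ()))
    neighbours.discard(focal)
    if sex_filter is not None:
        if individuals is None:
            raise ValueError("sex_filter requires the individuals mapping")
        neighbours = {b for b in neighbours if individuals[b].sex == sex_filter}
    neighbours &= set(r_matrix.ids)
    if not neighbours or focal not in r_matrix.ids:
        return float("nan")
    vals = np.array([r_matrix.r(focal, b) for b in sorted(neighbours)])
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if len(vals) else float("nan")


def relatedness_distance_slope(
    r_matrix: RelatednessMatrix,
    chamber_ids: list[str],
    distances: np.ndarray,
    assignment: dict[str, str],
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "two",
) -> PermTestResult:
    """Permutation test for a decline of relatedness with chamber distance.

    Observed statistic: OLS slope of dyadic relatedness on the Euclidean
    distance between the two birds' primary chambers.  The null permutes the
    bird-to-chamber assignment (a Mantel-type node-identity null), which
    conditions on both the relatedness structure and the chamber geometry.
    """
    birds = [b for b in r_matrix.ids if b in assignment]
    if len(birds) < 3:
        raise ValueError("need at least 3 assigned birds (3 dyads) for a slope")
    cidx = {c: i for i, c in enumerate(chamber_ids)}
    a = np.array([cidx[assignment[b]] for b in birds])
    if len(np.unique(a)) < 2:
        raise ValueError("all birds share one chamber; distance has no variance")
    r = r_matrix.submatrix(birds).values
    iu = np.triu_indices(len(birds), k=1)
    y = r[iu]
    keep = ~np.isnan(y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 valid dyads after dropping missing relatedness")

    def slope(ass: np.ndarray) -> float:
        x = distances[ass[iu[0]], ass[iu[1]]][keep]
        xv = x - x.mean()
        denom = xv @ xv
        if denom < 1e-12:
            return np.nan
        return float(xv @ (y[keep] - y[keep].mean()) / denom)

    observed = slope(a)
    rng = np.random.default_rng(seed)
    null = np.array([slope(rng.permutation(a)) for _ in range(n_perm)])
    null = null[~np.isnan(null)]
    return PermTestResult(
        "relatedness-distance OLS slope", observed, n_perm,
        _perm_pvalue(observed, null, tail), tail=tail, seed=seed,
        n=int(keep.sum()),
    )


def building_location_score(
    building_locations: dict[str, int],
    chamber_visits: dict[str, int],
    quartile_sets: dict[str, list[str]],
) -> float:
    """Visit-weighted fraction of building directed at a bird's own area.

    For each chamber ``u`` the bird uses (``chamber_visits``: entry counts),
    the fraction of its thatch-building events (``building_locations``:
    location chamber -> count) that landed above ``u`` itself or above the
    quartile of chambers nearest to ``u`` (``quartile_sets[u]``) is computed;
    fractions are averaged weighted by visit share.  With no visit records
    the fractions are averaged unweighted over the chambers in
    ``quartile_sets`` (with a warning).  The score lies in [0, 1] and is
    invariant to rescaling visit counts.
    """
    total_events = sum(building_locations.values())
    if total_events < 1:
        raise ValueError("bird has no building events")
    used = sorted(quartile_sets)
    if not used:
        raise ValueError("no used chambers supplied")
    total_visits = sum(chamber_visits.get(u, 0) for u in used)
    if total_visits == 0:
        warnings.warn(
            "builder has no visit records; falling back to an unweighted mean",
            stacklevel=2,
        )
        weights = {u: 1.0 / len(used) for u in used}
    else:
        weights = {u: chamber_visits.get(u, 0) / total_visits for u in used}
    score = 0.0
    for u in used:
        target = set(quartile_sets[u]) | {u}
        inside = sum(k for c, k in building_locations.items() if c in target)
        score += weights[u] * (inside / total_events)
    return score


def quartile_building_test(
    scores, mu: float = 0.25, alternative: str = "two-sided"
) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank of per-builder location scores vs mu.

    mu = 0.25 is the chance expectation of building above the nearest
    quarter of the colony's chambers.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if len(scores) == 0:
        raise ValueError("no builders with a location score")
    return wilcoxon_signed_rank(scores, mu=mu, alternative=alternative)


def builder_local_relatedness_contrast(
    local_r,
    builder_flags,
    sexes,
    colonies,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict[str, PermTestResult]:
    """Builders vs non-builders in local relatedness, separately per sex.

    A colony-stratified node-label permutation test per sex; returns a
    result per sex present with both classes non-empty.
    """
    local_r = np.asarray(local_r, dtype=float)
    builder_flags = np.asarray(builder_flags).astype(int)
    sexes = np.asarray(sexes)
    colonies = np.asarray(colonies)
    rng = np.random.default_rng(seed)
    out: dict[str, PermTestResult] = {}
    for sex in ("male", "female"):
        m = (sexes == sex) & ~np.isnan(local_r)
        if m.sum() == 0:
            continue
        flags = builder_flags[m]
        if flags.sum() == 0 or flags.sum() == m.sum():
            warnings.warn(f"{sex}: only one builder class present; contrast skipped",
                          stacklevel=2)
            continue
        out[sex] = node_label_test(
            local_r[m], flags, n_perm=n_perm, seed=int(rng.integers(2**31)),
            strata=colonies[m],
            statistic_name=f"{sex} builder - non-builder local relatedness",
        )
    return out


def colony_vs_population_relatedness(
    r_matrix: RelatednessMatrix,
    individuals: list[Individual],
    classes: tuple[str, ...] = ("all", "male", "female"),
    alternative: str = "two-sided",
) -> dict[str, dict]:
    """Within-colony vs population-level relatedness, by sex class.

    For each class (all birds, male-male dyads, female-female dyads) the
    population mean relatedness over all class dyads serves as mu, and each
    bird's mean relatedness to its within-colony class partners is tested
    against mu with a one-sample Wilcoxon signed-rank test — the individual
    is the sampling unit, the convention for this kind of colony-level
    contrast.  Reported mean and SD are over the pooled within-colony
    dyads, as relatedness summaries are conventionally printed.
    """
    by_colony: dict[str, list[str]] = {}
    for b in individuals:
        by_colony.setdefault(b.colony_id, []).append(b.id)
    if len(by_colony) < 2:
        raise ValueError("need at least 2 colonies to compare against the population")
    sex_of = {b.id: b.sex for b in individuals}
    genotyped = set(r_matrix.ids)
    out: dict[str, dict] = {}
    for cls in classes:
        if cls == "all":
            keep = [b for b in r_matrix.ids]
        else:
            keep = [b for b in r_matrix.ids if sex_of.get(b) == cls]
        if len(keep) < 2:
            continue
        pop_vals = r_matrix.offdiag(keep)
        pop_vals = pop_vals[~np.isnan(pop_vals)]
        mu = float(pop_vals.mean())
        indiv_vals = []  # per-bird mean relatedness to within-colony class partners
        dyad_vals = []
        n_colonies = 0
        for colony, members in sorted(by_colony.items()):
            ids = [b for b in members if b in genotyped and (cls == "all" or sex_of[b] == cls)]
            if len(ids) < 2:
                continue
            sub = r_matrix.submatrix(ids).values.copy()
            np.fill_diagonal(sub, np.nan)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows = np.nanmean(sub, axis=1)
            rows = rows[~np.isnan(rows)]
            if len(rows) == 0:
                continue
            n_colonies += 1
            indiv_vals.append(rows)
            vals = sub[np.triu_indices(len(ids), k=1)]
            dyad_vals.append(vals[~np.isnan(vals)])
        if n_colonies < 2:
            continue
        pooled = np.concatenate(dyad_vals)
        units = np.concatenate(indiv_vals)
        v, p = wilcoxon_signed_rank(units, mu=mu, alternative=alternative)
        out[cls] = {
            "population_mean": mu,
            "population_sd": float(pop_vals.std(ddof=1)),
            "colony_mean": float(pooled.mean()),
            "colony_sd": float(pooled.std(ddof=1)),
            "n_colonies": n_colonies,
            "n_dyads": int(len(pooled)),
            "n_individuals": int(len(units)),
            "V": v,
            "p_value": p,
        }
    return out
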
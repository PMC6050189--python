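"""Size-weighted hierarchical decomposition of q = 1 diversity.

Total (gamma) diversity of a spatially structured system is split, level by
level, into within-aggregate (alpha) and between-aggregate (beta)
components using the additivity of Shannon entropy over a nested
hierarchy.  With units (populations or communities) at level 1 nested in
aggregates up to the whole system at level L:

* unit weights are abundance shares ``w_j = N_+j / N_++`` (a unit counts
  in proportion to the individuals or allele copies it holds);
* ``H_alpha(l)`` is the weighted mean Shannon entropy of the pooled
  frequency vectors of the level-l aggregates, and ``D_alpha(l) =
  exp(H_alpha(l))`` is the corresponding effective number of elements;
* gamma at level l is alpha of the next level up, so beta is the ratio
  ``D_beta(l) = D_alpha(l+1) / D_alpha(l) >= 1`` — the effective number of
  distinct level-l aggregates per level-(l+1) aggregate — and the chain
  ``D_gamma = D_alpha(1) * prod_l D_beta(l)`` is exact;
* the differentiation ``Delta(l) = (H_alpha(l+1) - H_alpha(l)) / W(l)``
  normalises the entropy gap by its information-theoretic ceiling
  ``W(l)`` (the weighted entropy of child weights within each parent), so
  ``Delta`` lies in [0, 1] and equals the true proportion of non-shared
  elements for equally large, equally diverse aggregates.  With two
  levels and arbitrary weights it is the normalised mutual information
  between element identity and unit membership.

Genetic data are handled per locus (one allele-by-population table each)
and the effective numbers are averaged across loci afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import ValidationError, shannon_entropy

__all__ = [
    "AbundanceTable",
    "HierarchySpec",
    "LevelDecomposition",
    "allele_counts_from_genotypes",
    "compute_weights",
    "pooled_frequencies",
    "level_alpha_entropy",
    "weight_entropy_normalizer",
    "differentiation",
    "decompose",
    "average_over_loci",
]

logger = logging.getLogger(__name__)

# entropy gaps below this (nats) count as "no beta information"
_DEGENERATE_TOL = 1e-12


class AbundanceTable:
    """Non-negative element-by-unit abundance matrix.

    Rows are elements (species or alleles), columns are lowest-level units
    (communities or populations).  Cells may be counts of individuals,
    allele copies or biomass; only ratios matter downstream.
    """

    def __init__(self, data: pd.DataFrame, *, allow_empty_units: bool = False):
        if data.ndim != 2 or data.size == 0:
            raise ValidationError("abundance table must be a non-empty 2-D frame")
        values = data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("abundance table contains non-finite entries")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative abundance for element {data.index[r]!r} "
                f"in unit {data.columns[c]!r}"
            )
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate element identifiers: {dup}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate unit identifiers: {dup}")
        colsums = values.sum(axis=0)
        if not allow_empty_units and (colsums <= 0).any():
            empty = [data.columns[i] for i in np.flatnonzero(colsums <= 0)]
            raise ValidationError(f"units with zero total abundance: {empty}")
        self.data = data.astype(float)

    @classmethod
    def from_arrays(
        cls,
        counts: np.ndarray,
        elements: Sequence[str],
        units: Sequence[str],
        **kw,
    ) -> "AbundanceTable":
        frame = pd.DataFrame(np.asarray(counts, float), index=list(elements), columns=list(units))
        return cls(frame, **kw)

    @property
    def elements(self) -> list:
        return list(self.data.index)

    @property
    def units(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def drop_empty_units(self) -> tuple["AbundanceTable", list]:
        """Remove zero-total units; returns the reduced table and their ids."""
        colsums = self.values.sum(axis=0)
        dropped = [u for u, s in zip(self.units, colsums) if s <= 0]
        if not dropped:
            return self, []
        logger.warning("dropping units with zero abundance: %s", dropped)
        kept = self.data.drop(columns=dropped)
        return AbundanceTable(kept), dropped

    def restrict_units(self, units: Sequence) -> "AbundanceTable":
        missing = [u for u in units if u not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown units: {missing}")
        return AbundanceTable(self.data[list(units)], allow_empty_units=True)


class HierarchySpec:
    """Nested assignment of units to aggregates at each of L levels.

    ``level_names[0]`` is the unit level (each unit its own aggregate);
    ``level_names[-1]`` is the whole system, which must hold a single
    aggregate.  ``assignment`` maps every unit to its aggregate id at each
    level above the first, and the mapping must nest: two units sharing an
    aggregate at some level share aggregates at all higher levels.
    """

    def __init__(self, level_names: Sequence[str], assignment: pd.DataFrame):
        names = list(level_names)
        if len(names) < 2:
            raise ValidationError("hierarchy needs at least two levels (units + total)")
        if len(set(names)) != len(names):
            raise ValidationError("level names must be unique")
        if list(assignment.columns) != names[1:]:
            raise ValidationError(
                f"assignment columns {list(assignment.columns)} do not match "
                f"upper level names {names[1:]}"
            )
        if assignment.index.has_duplicates:
            dup = assignment.index[assignment.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate unit identifiers in hierarchy: {dup}")
        if assignment.isna().any().any():
            raise ValidationError("every unit must be assigned at every level")
        if assignment[names[-1]].nunique() != 1:
            raise ValidationError(
                f"top level {names[-1]!r} must contain exactly one aggregate, "
                f"found {sorted(map(str, assignment[names[-1]].unique()))}"
            )
        # nesting: each aggregate at level l must sit inside exactly one
        # aggregate at level l+1
        for lower, upper in zip(names[1:-1], names[2:]):
            parents = assignment.groupby(lower)[upper].nunique()
            bad = parents[parents > 1]
            if len(bad):
                raise ValidationError(
                    f"non-nested hierarchy: {lower!r} aggregate(s) "
                    f"{bad.index.tolist()} span multiple {upper!r} aggregates"
                )
        self.level_names = names
        self.assignment = assignment

    @classmethod
    def from_mapping(
        cls,
        level_names: Sequence[str],
        mapping: Mapping,
    ) -> "HierarchySpec":
        """Build from ``{unit: (level2_id, ..., levelL_id)}``."""
        frame = pd.DataFrame.from_dict(mapping, orient="index", columns=list(level_names)[1:])
        return cls(level_names, frame)

    @classmethod
    def two_level(cls, units: Sequence, total: str = "total") -> "HierarchySpec":
        """Flat hierarchy: every unit directly inside one pooled system."""
        frame = pd.DataFrame({"__unused__": [total] * len(units)}, index=list(units))
        frame.columns = [total if total != "unit" else "system"]
        return cls(["unit", frame.columns[0]], frame)

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    @property
    def units(self) -> list:
        return list(self.assignment.index)

    def groups_at(self, level: int) -> dict:
        """Aggregate id -> list of member units, for 1-based ``level``."""
        self._check_level(level)
        if level == 1:
            return {u: [u] for u in self.units}
        col = self.level_names[level - 1]
        return {
            agg: list(members.index)
            for agg, members in self.assignment.groupby(col, sort=False)
        }

    def children_of(self, level: int) -> dict:
        """Parent aggregate (level ``level+1``) -> child aggregate ids at ``level``."""
        self._check_level(level)
        if level >= self.n_levels:
            raise ValidationError("top level has no parent level")
        parent_col = self.level_names[level]
        if level == 1:
            grouped = self.assignment.groupby(parent_col, sort=False)
            return {agg: list(members.index) for agg, members in grouped}
        child_col = self.level_names[level - 1]
        out: dict = {}
        for (parent, child), _ in self.assignment.groupby([parent_col, child_col], sort=False):
            out.setdefault(parent, []).append(child)
        return out

    def restrict_units(self, units: Sequence) -> "HierarchySpec":
        missing = [u for u in units if u not in self.assignment.index]
        if missing:
            raise ValidationError(f"units missing from hierarchy: {missing}")
        return HierarchySpec(self.level_names, self.assignment.loc[list(units)])

    def _check_level(self, level: int) -> None:
        if not 1 <= level <= self.n_levels:
            raise ValidationError(
                f"level must be in 1..{self.n_levels}, got {level}"
            )

    def membership(self, units: Sequence) -> list[dict]:
        """Per-level group structure aligned to a unit order (cached).

        Returns one entry per level with ``onehot`` (units x groups
        indicator), ``groups`` (group ids) and ``parent`` (group index at
        the next level up, absent at the top).  This is the workhorse for
        the vectorised decomposition; results are cached per unit order
        since decompositions of many loci share one hierarchy.
        """
        key = tuple(units)
        cache = getattr(self, "_membership_cache", None)
        if cache is None:
            cache = self._membership_cache = {}
        if key in cache:
            return cache[key]
        sub = self.assignment.loc[list(units)]
        m = len(units)
        levels = []
        for l in range(self.n_levels):
            if l == 0:
                ids = list(units)
                codes = np.arange(m)
            else:
                col = sub[self.level_names[l]]
                ids = list(dict.fromkeys(col))
                pos = {g: i for i, g in enumerate(ids)}
                codes = np.array([pos[g] for g in col])
            onehot = np.zeros((m, len(ids)))
            onehot[np.arange(m), codes] = 1.0
            levels.append({"groups": ids, "codes": codes, "onehot": onehot})
        for l in range(self.n_levels - 1):
            child_codes, parent_codes = levels[l]["codes"], levels[l + 1]["codes"]
            parent = np.full(len(levels[l]["groups"]), -1, dtype=int)
            parent[child_codes] = parent_codes
            levels[l]["parent"] = parent
        cache[key] = levels
        return levels


@dataclass
class LevelDecomposition:
    """Per-level diversity components of a single table (or a loci average).

    Arrays are indexed by level, bottom-up: ``d_alpha[l]`` is the alpha
    diversity at level ``l+1`` (1-based), with ``d_alpha[-1] == d_gamma``;
    ``d_beta``, ``differentiation`` and ``beta_info_share`` have one entry
    per level below the top.
    """

    level_names: list[str]
    h_alpha: np.ndarray
    d_alpha: np.ndarray
    d_beta: np.ndarray
    differentiation: np.ndarray
    beta_info_share: np.ndarray
    d_gamma: float
    no_beta_information: bool = False
    per_locus: dict | None = None

    @property
    def n_levels(self) -> int:
        return len(self.level_names)

    def d_gamma_at(self, level: int) -> float:
        """Gamma diversity of level ``level`` (1-based): alpha of the level above."""
        if not 1 <= level <= self.n_levels:
            raise ValidationError(f"level must be in 1..{self.n_levels}")
        if level == self.n_levels:
            return self.d_gamma
        return float(self.d_alpha[level])

    def to_frame(self) -> pd.DataFrame:
        """Flat per-level table of all components (NaN where undefined)."""
        n = self.n_levels
        rows = []
        for l in range(n):
            rows.append(
                {
                    "level": l + 1,
                    "name": self.level_names[l],
                    "d_gamma": self.d_gamma_at(l + 1),
                    "d_alpha": float(self.d_alpha[l]),
                    "d_beta": float(self.d_beta[l]) if l < n - 1 else np.nan,
                    "differentiation": float(self.differentiation[l]) if l < n - 1 else np.nan,
                    "beta_info_share": float(self.beta_info_share[l]) if l < n - 1 else np.nan,
                }
            )
        return pd.DataFrame(rows)


def allele_counts_from_genotypes(
    genotypes: pd.DataFrame, known_units: Sequence | None = None
) -> dict:
    """Convert diploid genotype rows into one allele-count table per locus.

    ``genotypes`` needs columns ``unit``, ``locus``, ``allele1``,
    ``allele2`` (one row per individual per locus; rows with a missing
    call are excluded beforehand).  Each called allele contributes one
    copy, so column sums equal twice the number of genotyped individuals.
    """
    required = {"unit", "locus", "allele1", "allele2"}
    missing = required - set(genotypes.columns)
    if missing:
        raise ValidationError(f"genotype frame missing columns: {sorted(missing)}")
    if known_units is not None:
        unknown = sorted(set(genotypes["unit"]) - set(known_units))
        if unknown:
            raise ValidationError(f"unknown population id(s): {unknown}")
    long = pd.concat(
        [
            genotypes[["unit", "locus", "allele1"]].rename(columns={"allele1": "allele"}),
            genotypes[["unit", "locus", "allele2"]].rename(columns={"allele2": "allele"}),
        ],
        ignore_index=True,
    )
    tables = {}
    for locus, sub in long.groupby("locus", sort=False):
        counts = (
            sub.groupby(["allele", "unit"], sort=False).size().unstack(fill_value=0)
        )
        counts = counts.astype(float)
        tables[locus] = AbundanceTable(counts)
    return tables


def compute_weights(table: AbundanceTable, equal: bool = False) -> pd.Series:
    """Unit weights ``w_j = N_+j / N_++`` (or uniform with ``equal=True``)."""
    colsums = table.values.sum(axis=0)
    total = colsums.sum()
    if total <= 0:
        raise ValidationError("abundance table has zero total")
    if equal:
        w = np.full(len(colsums), 1.0 / len(colsums))
    else:
        w = colsums / total
    return pd.Series(w, index=table.data.columns)


def pooled_frequencies(
    table: AbundanceTable, weights: pd.Series, group: Iterable
) -> np.ndarray:
    """Pooled relative frequencies of a group of units.

    Computed as the weight mixture ``sum_j (w_j / w_group) p_{i|j}`` of the
    per-unit frequency vectors; with abundance-derived weights this equals
    renormalised summed raw counts.
    """
    members = list(group)
    if not members:
        raise ValidationError("group of units must not be empty")
    missing = [u for u in members if u not in table.data.columns]
    if missing:
        raise ValidationError(f"units not in table: {missing}")
    sub = table.data[members].to_numpy(dtype=float)
    colsums = sub.sum(axis=0)
    if (colsums <= 0).any():
        bad = [members[i] for i in np.flatnonzero(colsums <= 0)]
        raise ValidationError(f"zero-abundance units in group: {bad}")
    w = weights.loc[members].to_numpy(dtype=float)
    wg = w.sum()
    if wg <= 0:
        raise ValidationError("group has zero total weight")
    p = (sub / colsums) @ (w / wg)
    return p / p.sum()


def level_alpha_entropy(
    table: AbundanceTable, hierarchy: HierarchySpec, weights: pd.Series, level: int
) -> float:
    """Weighted mean Shannon entropy of the level's pooled aggregates.

    At level 1 this averages the per-unit entropies; at the top level it is
    the entropy of the fully pooled system (H_gamma).
    """
    groups = hierarchy.groups_at(level)
    h = 0.0
    for agg, members in groups.items():
        w_agg = float(weights.loc[members].sum())
        if w_agg <= 0:
            continue
        h += w_agg * shannon_entropy(pooled_frequencies(table, weights, members))
    return h


def weight_entropy_normalizer(
    hierarchy: HierarchySpec, weights: pd.Series, level: int
) -> float:
    """Ceiling ``W(l)`` for the level-l entropy gap.

    For each parent aggregate at level ``l+1``, the Shannon entropy of its
    children's relative weights, averaged with the parent weights:
    ``W(l) = sum_g w_g * H(w_c / w_g : c in g)``.  Reduces to ``ln N`` for
    N equally weighted children, recovering the normalised mutual
    information form of the differentiation measure.
    """
    groups_child = hierarchy.groups_at(level)
    w_child = {
        agg: float(weights.loc[members].sum()) for agg, members in groups_child.items()
    }
    total = 0.0
    for parent, children in hierarchy.children_of(level).items():
        wc = np.array([w_child[c] for c in children], dtype=float)
        wg = wc.sum()
        if wg <= 0:
            continue
        frac = wc[wc > 0] / wg
        total += wg * float(-(frac * np.log(frac)).sum())
    return total


def differentiation(
    table: AbundanceTable, hierarchy: HierarchySpec, weights: pd.Series, level: int
) -> float:
    """Normalised differentiation ``Delta(l)`` in [0, 1] at a single level."""
    if level >= hierarchy.n_levels:
        raise ValidationError("differentiation is undefined at the top level")
    gap = level_alpha_entropy(table, hierarchy, weights, level + 1) - level_alpha_entropy(
        table, hierarchy, weights, level
    )
    w_norm = weight_entropy_normalizer(hierarchy, weights, level)
    if w_norm <= 0:
        return 0.0
    return float(np.clip(gap / w_norm, 0.0, 1.0))


def decompose(
    table: AbundanceTable,
    hierarchy: HierarchySpec,
    *,
    equal_weights: bool = False,
) -> LevelDecomposition:
    """Full per-level gamma/alpha/beta decomposition of one table.

    Alpha entropies are computed once per level and everything else is
    derived from them (entropy differences rather than logs of rounded
    effective numbers, to avoid cancellation).
    """
    t_units = set(table.units)
    h_units = set(hierarchy.units)
    if t_units != h_units:
        only_t = sorted(map(str, t_units - h_units))
        only_h = sorted(map(str, h_units - t_units))
        raise ValidationError(
            f"table and hierarchy unit sets differ (table-only: {only_t}, "
            f"hierarchy-only: {only_h})"
        )
    values = table.values
    colsums = values.sum(axis=0)
    if equal_weights:
        w = np.full(values.shape[1], 1.0 / values.shape[1])
    else:
        w = colsums / colsums.sum()
    freqs_w = (values / colsums) * w  # column j holds w_j * p_{i|j}
    levels = hierarchy.membership(table.units)
    n = hierarchy.n_levels
    h_alpha = np.empty(n)
    w_norms = np.empty(n - 1)
    group_w: list[np.ndarray] = []
    for l, lev in enumerate(levels):
        pooled = freqs_w @ lev["onehot"]  # elements x groups, columns sum to w_g
        w_g = w @ lev["onehot"]
        group_w.append(w_g)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_g = np.where(w_g > 0, pooled / np.where(w_g > 0, w_g, 1.0), 0.0)
            logp = np.where(p_g > 0, np.log(p_g), 0.0)
        h_alpha[l] = float(-(w_g * (p_g * logp).sum(axis=0)).sum())
    for l in range(n - 1):
        wc, parent = group_w[l], levels[l]["parent"]
        wp = group_w[l + 1][parent]
        pos = wc > 0
        w_norms[l] = float((wc[pos] * (np.log(wp[pos]) - np.log(wc[pos]))).sum())
    d_alpha = np.exp(h_alpha)
    d_gamma = float(d_alpha[-1])
    gaps = np.clip(np.diff(h_alpha), 0.0, None)  # >= 0 by concavity of entropy
    gaps[gaps <= _DEGENERATE_TOL] = 0.0  # flush rounding noise at identical levels
    d_beta = np.exp(gaps)
    total_gap = float(h_alpha[-1] - h_alpha[0])
    degenerate = total_gap <= _DEGENERATE_TOL
    if degenerate:
        shares = np.zeros(n - 1)
    else:
        shares = gaps / total_gap
    delta = np.array(
        [
            0.0 if w_norms[l] <= 0 else float(np.clip(gaps[l] / w_norms[l], 0.0, 1.0))
            for l in range(n - 1)
        ]
    )
    if degenerate:
        logger.info("no beta information: all units share one composition")
    return LevelDecomposition(
        level_names=list(hierarchy.level_names),
        h_alpha=h_alpha,
        d_alpha=d_alpha,
        d_beta=d_beta,
        differentiation=delta,
        beta_info_share=shares,
        d_gamma=d_gamma,
        no_beta_information=degenerate,
    )


def decompose_per_locus(
    tables: Mapping,
    hierarchy: HierarchySpec,
    *,
    equal_weights: bool = False,
) -> LevelDecomposition:
    """Decompose each locus table, then average the effective numbers.

    Units with zero count at a particular locus are dropped from that
    locus (weights renormalise automatically); a warning is logged.
    """
    decomps = []
    for locus, table in tables.items():
        kept, dropped = table.drop_empty_units()
        if dropped:
            logger.warning("locus %s: dropped empty units %s", locus, dropped)
        hier = hierarchy.restrict_units(kept.units) if dropped else hierarchy
        decomps.append(decompose(kept, hier, equal_weights=equal_weights))
    return average_over_loci(decomps, loci=list(tables.keys()))


def average_over_loci(
    decomps: Sequence[LevelDecomposition], loci: Sequence | None = None
) -> LevelDecomposition:
    """Arithmetic mean of the reported quantities across loci.

    Effective numbers (gamma, alpha, beta) and differentiation are averaged
    directly; per-locus results are retained on the returned object.  Note
    the multiplicative chain is a per-locus identity and is *not* preserved
    by averaging (a mean of products is not the product of means).
    """
    if not decomps:
        raise ValidationError("no decompositions to average")
    names = decomps[0].level_names
    for d in decomps[1:]:
        if d.level_names != names:
            raise ValidationError(
                f"mismatched hierarchies: {d.level_names} vs {names}"
            )
    if len(decomps) == 1:
        single = decomps[0]
        single.per_locus = {(loci[0] if loci else 0): single}
        return single
    keys = loci if loci is not None else list(range(len(decomps)))
    mean = lambda attr: np.mean([getattr(d, attr) for d in decomps], axis=0)
    return LevelDecomposition(
        level_names=list(names),
        h_alpha=mean("h_alpha"),
        d_alpha=mean("d_alpha"),
        d_beta=mean("d_beta"),
        differentiation=mean("differentiation"),
        beta_info_share=mean("beta_info_share"),
        d_gamma=float(np.mean([d.d_gamma for d in decomps])),
        no_beta_information=all(d.no_beta_information for d in decomps),
        per_locus=dict(zip(keys, decomps)),
    )
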
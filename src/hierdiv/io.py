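"""CSV / Newick / JSON input-output for the decomposition pipeline.

File conventions: UTF-8, comma-separated, ``#`` comment lines ignored,
decimal points only.  Three tabular inputs are understood:

* wide abundance CSV — first column element id, remaining columns one per
  unit (header row required); cells are non-negative counts, biomass or
  relative abundances (columns all summing to ~1 are accepted and
  flagged);
* long genetic CSV — columns ``locus,unit,allele,count``, split into one
  abundance table per locus;
* genotype CSV — columns ``individual,unit,locus,allele1,allele2`` for
  diploid calls, converted to per-locus allele-copy tables;
* structure CSV — one row per unit, columns ``unit,<level2>,...``
  upward; if the rightmost column still has several aggregates a single
  ``ecosystem`` top level is appended.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import ValidationError
from .partition import (
    AbundanceTable,
    HierarchySpec,
    LevelDecomposition,
    allele_counts_from_genotypes,
)
from .phylo import PhyloTreeModel

__all__ = [
    "read_abundance_csv",
    "read_locus_csv",
    "read_genotype_csv",
    "read_structure_csv",
    "read_tree",
    "results_to_dict",
    "write_results",
    "read_results_json",
]

logger = logging.getLogger(__name__)


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    try:
        return pd.read_csv(path, comment="#", skip_blank_lines=True)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValidationError(f"{path}: malformed CSV ({exc})") from exc


def read_abundance_csv(path) -> AbundanceTable:
    """Wide element-by-unit table; relative-abundance input is accepted."""
    frame = _read_csv(path)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need an element column plus at least one unit")
    frame = frame.set_index(frame.columns[0])
    try:
        values = frame.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: non-numeric abundance cell ({exc})") from exc
    bad = np.argwhere(values.to_numpy() < 0)
    if bad.size:
        r, c = bad[0]
        raise ValidationError(
            f"{path}: negative abundance at row {r + 2} "
            f"(element {values.index[r]!r}, unit {values.columns[c]!r})"
        )
    colsums = values.sum(axis=0)
    if np.allclose(colsums, 1.0, atol=1e-6) and (values.to_numpy() <= 1.0).all():
        logger.info("%s: columns sum to 1 — treating input as relative abundances", path)
    table = AbundanceTable(values, allow_empty_units=True)
    table, dropped = table.drop_empty_units()
    if dropped:
        logger.warning("%s: ignored empty units %s", path, dropped)
    return table


def read_locus_csv(path) -> dict:
    """Long-format genetic CSV -> ``{locus: AbundanceTable}``."""
    frame = _read_csv(path)
    required = {"locus", "unit", "allele", "count"}
    if not required <= set(frame.columns):
        raise ValidationError(
            f"{path}: long-format file needs columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    frame["count"] = pd.to_numeric(frame["count"])
    neg = frame.index[frame["count"] < 0]
    if len(neg):
        raise ValidationError(f"{path}: negative count at row {int(neg[0]) + 2}")
    tables = {}
    for locus, sub in frame.groupby("locus", sort=False):
        wide = sub.pivot_table(
            index="allele", columns="unit", values="count", aggfunc="sum", fill_value=0.0
        )
        tables[locus] = AbundanceTable(wide, allow_empty_units=True)
    return tables


def read_genotype_csv(path, known_units=None) -> dict:
    """Diploid genotype CSV -> per-locus allele-copy tables."""
    frame = _read_csv(path)
    return allele_counts_from_genotypes(frame, known_units=known_units)


def read_structure_csv(path) -> HierarchySpec:
    """Structure CSV -> validated hierarchy (nesting enforced)."""
    frame = _read_csv(path)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: need a unit column plus at least one level")
    unit_col = frame.columns[0]
    frame = frame.astype(str).set_index(unit_col)
    level_names = [unit_col, *frame.columns]
    if frame[frame.columns[-1]].nunique() > 1:
        frame = frame.assign(ecosystem="ecosystem")
        level_names.append("ecosystem")
    return HierarchySpec(level_names, frame)


def read_tree(path) -> PhyloTreeModel:
    """Rooted Newick tree."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    return PhyloTreeModel.from_newick(str(path), is_path=True)


def _level_records(dec: LevelDecomposition) -> list[dict]:
    records = []
    n = dec.n_levels
    for l in range(n):
        rec = {
            "level": l + 1,
            "name": dec.level_names[l],
            "d_gamma": dec.d_gamma_at(l + 1),
            "d_alpha": float(dec.d_alpha[l]),
        }
        if l < n - 1:
            rec["d_beta"] = float(dec.d_beta[l])
            rec["differentiation"] = float(dec.differentiation[l])
            rec["beta_info_share"] = float(dec.beta_info_share[l])
        records.append(rec)
    return records


def results_to_dict(
    dec: LevelDecomposition,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Machine-readable result document (JSON-serialisable)."""
    doc = {
        "tool": "hierdiv",
        "version": __version__,
        "config": dict(config or {}),
        "seed": seed,
        "levels": list(dec.level_names),
        "d_gamma": float(dec.d_gamma),
        "no_beta_information": bool(dec.no_beta_information),
        "per_level": _level_records(dec),
    }
    if dec.per_locus:
        doc["per_locus"] = {
            str(locus): {
                "d_gamma": float(d.d_gamma),
                "per_level": _level_records(d),
            }
            for locus, d in dec.per_locus.items()
        }
    return doc


def _results_frame(dec: LevelDecomposition) -> pd.DataFrame:
    frames = []
    if dec.per_locus:
        for locus, d in dec.per_locus.items():
            f = d.to_frame()
            f.insert(0, "locus", str(locus))
            frames.append(f)
        avg = dec.to_frame()
        avg.insert(0, "locus", "average")
        frames.append(avg)
    else:
        f = dec.to_frame()
        f.insert(0, "locus", "all")
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def write_results(
    dec: LevelDecomposition,
    out_json=None,
    out_csv=None,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """Write JSON and/or flat CSV; returns the JSON document.

    Floats are serialised with shortest round-trip repr, so re-reading the
    JSON reproduces every number bitwise.
    """
    doc = results_to_dict(dec, config=config, seed=seed)
    if out_json is not None:
        Path(out_json).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
    if out_csv is not None:
        _results_frame(dec).to_csv(out_csv, index=False)
    return doc


def read_results_json(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
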
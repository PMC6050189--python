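"""Small built-in example data sets, generated programmatically.

These back the worked examples, the test suite and the CLI demos; nothing
here is measured data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .partition import AbundanceTable, HierarchySpec
from .simulate import SimulationConfig, run_experiment


def shared_allele_example(
    n_units: int = 2, s: int = 10, shared: int = 4, copies_per_allele: float = 10.0
):
    """Equally diverse units with a known proportion of non-shared elements.

    Each of ``n_units`` units carries ``s`` equally frequent alleles:
    ``shared`` of them common to every unit, the rest globally unique.
    The true proportion of non-shared alleles per unit is ``1 - shared/s``
    and the q = 1 differentiation must return exactly that (0.6 for the
    default two-unit, 10-allele, 4-shared case).
    """
    if not 0 <= shared <= s:
        raise ValueError("shared must lie in [0, s]")
    units = [f"pop{j + 1}" for j in range(n_units)]
    shared_ids = [f"shared{i + 1}" for i in range(shared)]
    rows = {a: [copies_per_allele] * n_units for a in shared_ids}
    for j in range(n_units):
        for i in range(s - shared):
            rows[f"unique_{units[j]}_{i + 1}"] = [
                copies_per_allele if k == j else 0.0 for k in range(n_units)
            ]
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = units
    table = AbundanceTable(frame)
    hierarchy = HierarchySpec.from_mapping(
        ["population", "ecosystem"], {u: ("eco",) for u in units}
    )
    return table, hierarchy


def toy_ecosystem():
    """Three-level toy: 4 communities in 2 regions, 5 species, uneven sizes."""
    frame = pd.DataFrame(
        {
            "c1": [30.0, 10.0, 5.0, 0.0, 0.0],
            "c2": [20.0, 20.0, 0.0, 5.0, 0.0],
            "c3": [0.0, 5.0, 25.0, 10.0, 5.0],
            "c4": [5.0, 0.0, 10.0, 30.0, 10.0],
        },
        index=["sp1", "sp2", "sp3", "sp4", "sp5"],
    )
    table = AbundanceTable(frame)
    hierarchy = HierarchySpec.from_mapping(
        ["community", "region", "ecosystem"],
        {
            "c1": ("west", "eco"),
            "c2": ("west", "eco"),
            "c3": ("east", "eco"),
            "c4": ("east", "eco"),
        },
    )
    return table, hierarchy


def toy_tree_newick() -> str:
    """Ultrametric 5-tip tree (depth 4) matching ``toy_ecosystem`` species."""
    return "((sp1:2,sp2:2):2,((sp3:1,sp4:1):1,sp5:2):2);"


def write_example_files(out_dir) -> dict:
    """Materialise all fixtures as CSV/Newick files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    table, hierarchy = shared_allele_example()
    abundance = table.data.copy()
    abundance.insert(0, "allele", abundance.index)
    paths["shared_abundance"] = out / "shared_allele_abundance.csv"
    abundance.to_csv(paths["shared_abundance"], index=False)
    structure = hierarchy.assignment.copy()
    structure.insert(0, "population", structure.index)
    paths["shared_structure"] = out / "shared_allele_structure.csv"
    structure.to_csv(paths["shared_structure"], index=False)

    table3, hier3 = toy_ecosystem()
    ab3 = table3.data.copy()
    ab3.insert(0, "species", ab3.index)
    paths["toy_abundance"] = out / "toy_ecosystem_abundance.csv"
    ab3.to_csv(paths["toy_abundance"], index=False)
    st3 = hier3.assignment.copy()
    st3.insert(0, "community", st3.index)
    paths["toy_structure"] = out / "toy_ecosystem_structure.csv"
    st3.to_csv(paths["toy_structure"], index=False)

    paths["toy_tree"] = out / "toy_tree.nwk"
    paths["toy_tree"].write_text(toy_tree_newick() + "\n", encoding="utf-8")

    mini = run_experiment(
        SimulationConfig(n_reps=3, n_loci=2, seed=20260928), deltas=(0.5, 4.0)
    )
    paths["mini_simulation"] = out / "mini_simulation.csv"
    mini.to_csv(paths["mini_simulation"], index=False)
    return paths
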
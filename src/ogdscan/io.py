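"""Tabular I/O: trait tables, call tables, grid matrices, clade files."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, FrozenSet, List, Sequence

import pandas as pd

from .factors import HABITAT_CATEGORIES
from .scan import GridResult, OGDCall
from .treecore import BranchRef, Tree

__all__ = [
    "read_trait_table",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_grid_tsv",
    "read_clade_file",
    "write_evaluation_tsv",
    "write_site_loglik_tsv",
]

TRAIT_COLUMNS = ["gc_percent", "genome_mb", *HABITAT_CATEGORIES]


def read_trait_table(path) -> pd.DataFrame:
    """TSV with columns: taxon, gc_percent, genome_mb, hab_* (6), [interactions]."""
    df = pd.read_csv(path, sep="\t")
    if "taxon" not in df.columns:
        raise ValueError("trait table needs a 'taxon' column")
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table lacks columns: {missing}")
    df = df.set_index("taxon")
    if df.index.duplicated().any():
        raise ValueError("duplicate taxa in trait table")
    if (df[HABITAT_CATEGORIES] < 0).any().any():
        raise ValueError("habitat counts must be nonnegative")
    return df


def write_calls_tsv(calls: Sequence[OGDCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\trecipient_clade\tdonor_clade\telw\tdistance\tfiltered_reason\n")
        for c in calls:
            fh.write(
                f"{c.family}\t{','.join(sorted(c.recipient.clade))}\t"
                f"{','.join(sorted(c.donor.clade))}\t{c.elw:.6f}\t{c.distance:.6f}\t"
                f"{c.filtered_reason}\n"
            )


def read_calls_tsv(path) -> List[OGDCall]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        out.append(
            OGDCall(
                family=row["family"],
                recipient=BranchRef(frozenset(row["recipient_clade"].split(","))),
                donor=BranchRef(frozenset(row["donor_clade"].split(","))),
                elw=float(row["elw"]),
                distance=float(row["distance"]),
                filtered_reason=row.get("filtered_reason", ""),
            )
        )
    return out


def write_grid_tsv(grid: GridResult, path) -> None:
    df = pd.DataFrame(
        grid.counts,
        index=[f"elw_{e:g}" for e in grid.elw_grid],
        columns=[f"dist_{d:g}" for d in grid.distance_grid],
    )
    df.to_csv(path, sep="\t")


def write_evaluation_tsv(evaluation, path) -> None:
    """Audit export of one (family, branch) evaluation: per-candidate ELW table."""
    with open(path, "w") as fh:
        fh.write(
            "family\tpruned_branch\tcandidate\tinsertion_branch\t"
            "log_likelihood\telw\tdistance\tis_original\n"
        )
        recip = ",".join(sorted(evaluation.pruned_branch.clade))
        for i, cand in enumerate(evaluation.candidates):
            ins = ",".join(sorted(cand.point.branch.clade))
            fh.write(
                f"{evaluation.family}\t{recip}\t{i}\t{ins}\t"
                f"{cand.log_likelihood:.6f}\t{cand.elw:.6f}\t"
                f"{cand.distance:.6f}\t{int(cand.is_original)}\n"
            )


def write_site_loglik_tsv(evaluation, path) -> None:
    """Audit export of the sitewise log-likelihood table (candidates x sites)."""
    mat = pd.DataFrame(
        [c.site_logl for c in evaluation.candidates],
        index=[f"candidate_{i}" for i in range(len(evaluation.candidates))],
    )
    mat.columns = [f"site_{j}" for j in range(mat.shape[1])]
    mat.to_csv(path, sep="\t", float_format="%.8f")


def read_clade_file(path) -> Dict[str, FrozenSet[str]]:
    """TSV: clade name, comma-separated leaf labels."""
    out: Dict[str, FrozenSet[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, leaves = line.split("\t")
        out[name] = frozenset(x.strip() for x in leaves.split(",") if x.strip())
    return out
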
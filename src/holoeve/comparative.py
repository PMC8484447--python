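"""Cross-species differential-expression comparisons.

Covers threshold-based DEG selection (strict FDR < 0.001 or flexible
FDR < 0.01, both with |logFC| > 2), lining up ortholog log-fold-changes
across species against a chosen baseline species, and counting
KEGG-Ortholog (KO) overlaps between species as Venn-region counts.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["select_degs", "align_ortholog_logfc", "shared_ko_sets"]

# DESeq2-style exports are accepted through column aliases.
_COLUMN_ALIASES = {
    "log2FoldChange": "logFC",
    "log2foldchange": "logFC",
    "lfc": "logFC",
    "padj": "fdr",
    "FDR": "fdr",
    "qvalue": "fdr",
}

STRICT_FDR = 0.001
FLEXIBLE_FDR = 0.01


def _normalise_columns(table: pd.DataFrame) -> pd.DataFrame:
    renames = {c: _COLUMN_ALIASES[c] for c in table.columns
               if c in _COLUMN_ALIASES}
    return table.rename(columns=renames)


def select_degs(
    table: pd.DataFrame,
    fdr_max: float = STRICT_FDR,
    abs_lfc_min: float = 2.0,
) -> pd.DataFrame:
    """Filter a DE table to significant genes.

    Keeps rows with ``fdr < fdr_max`` and ``|logFC| > abs_lfc_min`` (both
    strict).  The fold-change rule is two-tailed: strong up- or
    down-regulation both qualify.
    """
    table = _normalise_columns(table)
    missing = [c for c in ("gene_id", "logFC", "fdr") if c not in table.columns]
    if missing:
        raise KeyError(f"DE table is missing required columns: {missing}")
    bad = table["fdr"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    mask = (table["fdr"] < fdr_max) & (table["logFC"].abs() > abs_lfc_min)
    return table[mask.fillna(False)].copy()


def align_ortholog_logfc(
    orthogroup_map: pd.DataFrame,
    per_species_tables: dict[str, pd.DataFrame],
    baseline_species: str,
    fdr_max: float = FLEXIBLE_FDR,
    abs_lfc_min: float = 2.0,
) -> pd.DataFrame:
    """Line up ortholog log-fold-changes across species.

    ``orthogroup_map`` has columns (orthogroup_id, species, gene_id); rows
    of the output are the orthogroups with at least one member significant
    in the baseline species (at ``fdr_max`` / ``abs_lfc_min``).  For every
    species the output holds the logFC of its member — or the list of all
    member logFCs, flagged ``variable_<species>``, when several transcripts
    share the orthogroup (variable expression from multiple transcripts
    with the same functional annotation).  Missing orthologs stay null.
    """
    if baseline_species not in per_species_tables:
        raise KeyError(
            f"baseline species {baseline_species!r} absent from DE tables"
        )
    omap = orthogroup_map
    need = [c for c in ("orthogroup_id", "species", "gene_id")
            if c not in omap.columns]
    if need:
        raise KeyError(f"orthogroup map missing columns: {need}")

    tables = {
        sp: _normalise_columns(t).set_index("gene_id")
        for sp, t in per_species_tables.items()
    }
    base_sig = set(
        select_degs(per_species_tables[baseline_species],
                    fdr_max=fdr_max, abs_lfc_min=abs_lfc_min)["gene_id"]
    )
    base_map = omap[omap["species"] == baseline_species]
    keep_ogs = sorted(set(
        base_map.loc[base_map["gene_id"].isin(base_sig), "orthogroup_id"]
    ))

    species = list(per_species_tables)
    rows = []
    for og in keep_ogs:
        row: dict = {"orthogroup_id": og}
        for sp in species:
            genes = omap.loc[
                (omap["orthogroup_id"] == og) & (omap["species"] == sp),
                "gene_id",
            ].tolist()
            tab = tables[sp]
            vals = [float(tab.at[g, "logFC"]) for g in genes if g in tab.index]
            sigs = [
                g in tab.index
                and tab.at[g, "fdr"] < fdr_max
                and abs(tab.at[g, "logFC"]) > abs_lfc_min
                for g in genes
            ]
            if not vals:
                row[f"logfc_{sp}"] = np.nan
                row[f"variable_{sp}"] = False
                row[f"significant_{sp}"] = False
            elif len(vals) == 1:
                row[f"logfc_{sp}"] = vals[0]
                row[f"variable_{sp}"] = False
                row[f"significant_{sp}"] = bool(sigs[0])
            else:
                row[f"logfc_{sp}"] = vals  # all values retained
                row[f"variable_{sp}"] = True
                row[f"significant_{sp}"] = bool(any(sigs))
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("orthogroup_id")
    out.attrs["baseline_species"] = baseline_species
    return out


def shared_ko_sets(per_species_kos: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive Venn-region counts of KO identifiers across species.

    Each KO counts once per species regardless of transcript multiplicity.
    Every non-empty subset of species yields one row: the KOs present in
    exactly those species and no other.  Region counts therefore sum to
    the size of the union of all sets.
    """
    species = list(per_species_kos)
    sets = {sp: set(per_species_kos[sp]) for sp in species}
    rows = []
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            inside = set.intersection(*(sets[sp] for sp in combo))
            outside = set.union(
                set(), *(sets[sp] for sp in species if sp not in combo)
            )
            exclusive = inside - outside
            rows.append(
                {"species_set": "+".join(combo), "n_species": r,
                 "count": len(exclusive), "kos": tuple(sorted(exclusive))}
            )
    return pd.DataFrame(rows)
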
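"""Readers and writers for every format the pipeline touches.

One tabular dialect is used throughout: tab-separated UTF-8 with '.'
decimals, no quoting, missing values serialised as ``NA`` and provenance
recorded in leading ``#`` comment lines (version, seed, config hash — no
timestamps, so re-runs are byte-identical).  Every writer's output is
accepted by the corresponding reader.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .phylogeny import Phylogeny

__all__ = [
    "RunConfig",
    "read_newick",
    "write_newick",
    "read_table",
    "write_table",
    "read_expression",
    "write_expression",
]

NA_REP = "NA"


def read_newick(path) -> Phylogeny:
    """Parse and validate a newick file (tolerates Windows line endings)."""
    return Phylogeny.from_file(path)


def write_newick(tree: Phylogeny, path) -> None:
    tree.write(path)


def write_table(
    df: pd.DataFrame,
    path,
    index: bool = True,
    provenance: dict | None = None,
    float_format: str = "%.10g",
) -> None:
    """Write a TSV with optional '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for k, v in (provenance or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=NA_REP,
                  float_format=float_format, lineterminator="\n")


def read_table(path, index_col=None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` ('#' lines skipped)."""
    return pd.read_csv(
        path, sep="\t", comment="#", index_col=index_col,
        na_values=[NA_REP], keep_default_na=False,
    )


def write_expression(
    expr: pd.DataFrame, path, provenance: dict | None = None
) -> None:
    """Genes-as-rows, samples-as-columns expression TSV."""
    write_table(expr, path, index=True, provenance=provenance)


def read_expression(path, meta_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read an expression matrix and its sample metadata, cross-validated.

    Every matrix column must appear in the metadata's ``sample_id``
    column; all matrix cells must be numeric and finite.
    """
    expr = read_table(path, index_col=0)
    meta = read_table(meta_path)
    need = [c for c in ("sample_id", "species", "condition", "replicate")
            if c not in meta.columns]
    if need:
        raise ValueError(f"metadata missing columns: {need}")
    known = set(meta["sample_id"])
    missing = [c for c in expr.columns if c not in known]
    if missing:
        raise ValueError(
            f"samples in matrix missing from metadata: {missing}"
        )
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        # locate the offending cell for the error message
        for col in expr.columns:
            coerced = pd.to_numeric(expr[col], errors="coerce")
            bad = coerced.isna() & expr[col].notna()
            if bad.any():
                row = expr.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric expression value at gene {row!r}, "
                    f"sample {col!r}"
                ) from exc
        raise
    # metadata restricted and ordered to the matrix columns
    meta = meta.set_index("sample_id").loc[list(expr.columns)].reset_index()
    return expr, meta


# ----------------------------------------------------------------------
# Run configuration
# ----------------------------------------------------------------------
_STAGES = ("simulate", "eve", "eve_r", "everest", "qmf", "redundancy", "physio")


@dataclass
class RunConfig:
    """Validated pipeline configuration (strict schema: unknown keys reject).

    Input paths may be omitted when the ``simulate`` stage is requested,
    in which case the simulator's outputs feed the downstream stages.
    """

    outdir: str = "holoeve_out"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(_STAGES))
    tree: str | None = None
    expression: str | None = None
    metadata: str | None = None
    annotation: str | None = None
    tpm: str | None = None
    physiology: str | None = None
    # simulate stage
    n_genes: int = 300
    n_replicates_per_condition: int = 3
    gene_class_proportions: dict = field(
        default_factory=lambda: {"null": 0.7, "divergence": 0.1,
                                 "diversity": 0.1, "responsive": 0.1}
    )
    # thresholds
    p_div: float = 0.05
    p_change: float = 0.05
    p_threshold: float = 0.05
    fdr_max: float = 0.001
    abs_lfc_min: float = 2.0
    min_tpm: float = 10.0
    min_samples: int = 2
    # mode switches
    qmf_statistic: str = "sum"
    qmf_denominator: str = "member_kegg_total"
    everest_sign: str = "treatment_minus_control"
    everest_pairing: str = "by_replicate_label"

    def __post_init__(self):
        for name in ("p_div", "p_change", "p_threshold", "fdr_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.abs_lfc_min < 0 or self.min_tpm < 0 or self.min_samples < 0:
            raise ValueError("thresholds must be non-negative")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(
                f"unknown stages {sorted(unknown)}; valid: {list(_STAGES)}"
            )
        if self.qmf_statistic not in ("sum", "median"):
            raise ValueError("qmf_statistic must be 'sum' or 'median'")
        if self.qmf_denominator not in ("member_kegg_total", "library_total"):
            raise ValueError("bad qmf_denominator")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        The output directory is excluded so that identical analyses
        written to different locations carry the same provenance.
        """
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
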
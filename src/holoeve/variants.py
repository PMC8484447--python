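"""Stimulus-aware extensions of the EVE divergence test.

EVE-R ("EVE-Response") looks for genes whose expression baseline already
diverges between species under ambient conditions *and* changes after the
stimulus in at least one species: the divergence test runs on control
samples only, and retained genes are filtered by a per-species two-sided
Welch t-test of control vs treatment.

EVEReSt ("EVE in Response to Stimulus") instead tests the *response*
itself: per-species paired treatment-minus-control expression differences
become the individuals fed to the divergence test, so species-specific
intrinsic responses are detected even for genes with identical ambient
baselines.  Because the OU likelihood is symmetric under global negation,
the subtraction direction only flips the sign of the fitted optimum; both
directions are supported and recorded in the output provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import eve
from .eve import SampleLayout
from .phylogeny import Phylogeny

__all__ = [
    "ResponseMatrix",
    "welch_t_test",
    "compute_response",
    "run_eve_r",
    "run_everest",
]

SIGNS = ("treatment_minus_control", "control_minus_treatment")
PAIRINGS = ("by_replicate_label", "by_sorted_order")


@dataclass
class ResponseMatrix:
    """Per-pair expression responses with their species layout.

    ``values`` is a genes x pairs DataFrame; column ``i`` holds the paired
    difference for species ``species[i]`` and replicate ``replicates[i]``.
    """

    values: pd.DataFrame
    species: tuple[str, ...]
    replicates: tuple[str, ...]
    sign: str
    pairing: str

    @property
    def layout(self) -> SampleLayout:
        return SampleLayout(
            species=self.species, sample_ids=tuple(self.values.columns)
        )


def welch_t_test(x, y) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test.

    Returns ``(t, p)`` with Satterthwaite degrees of freedom.  If both
    groups have zero variance the test degenerates: equal means give
    ``p = 1`` by convention, unequal means the limit ``p = 0``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in t-test input")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        warnings.warn(
            "zero variance in both groups with unequal means: p -> 0 limit",
            RuntimeWarning,
        )
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def _split_conditions(meta: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    conds = set(meta["condition"])
    missing = {"control", "treatment"} - conds
    if missing:
        raise ValueError(f"missing condition(s) in metadata: {sorted(missing)}")
    return (meta[meta["condition"] == "control"],
            meta[meta["condition"] == "treatment"])


def compute_response(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    sign: str = "treatment_minus_control",
    pairing: str = "by_replicate_label",
) -> ResponseMatrix:
    """Paired per-species treatment-vs-control expression differences.

    Under ``by_replicate_label`` a control sample pairs with the
    same-species treatment sample sharing its replicate label (the paired
    colony-fragment design); ``by_sorted_order`` pairs samples in sorted
    sample-id order for unlabelled data.  Unpaired samples are dropped
    with a warning; a species with no complete pair raises.
    """
    if sign not in SIGNS:
        raise ValueError(f"sign must be one of {SIGNS}")
    if pairing not in PAIRINGS:
        raise ValueError(f"pairing must be one of {PAIRINGS}")
    ctrl, trt = _split_conditions(meta)

    cols, col_species, col_reps = [], [], []
    dropped = []
    data = {}
    for sp in dict.fromkeys(meta["species"]):
        c = ctrl[ctrl["species"] == sp]
        t = trt[trt["species"] == sp]
        if pairing == "by_replicate_label":
            common = [r for r in c["replicate"] if r in set(t["replicate"])]
            dropped += [
                f"{sp}:{r}" for r in
                set(c["replicate"]).symmetric_difference(set(t["replicate"]))
            ]
            pairs = [
                (c.loc[c["replicate"] == r, "sample_id"].iloc[0],
                 t.loc[t["replicate"] == r, "sample_id"].iloc[0], r)
                for r in common
            ]
        else:
            cs = sorted(c["sample_id"])
            ts = sorted(t["sample_id"])
            k = min(len(cs), len(ts))
            dropped += cs[k:] + ts[k:]
            pairs = [(cs[i], ts[i], f"p{i + 1}") for i in range(k)]
        if not pairs:
            raise ValueError(f"no complete control/treatment pair for species {sp!r}")
        for cid, tid, r in pairs:
            diff = expr[tid] - expr[cid]
            if sign == "control_minus_treatment":
                diff = -diff
            name = f"{sp}_{r}"
            data[name] = diff
            cols.append(name)
            col_species.append(sp)
            col_reps.append(r)
    if dropped:
        warnings.warn(
            f"unpaired samples dropped from response matrix: {sorted(dropped)}",
            RuntimeWarning,
        )
    values = pd.DataFrame(data, index=expr.index)[cols]
    return ResponseMatrix(
        values=values, species=tuple(col_species), replicates=tuple(col_reps),
        sign=sign, pairing=pairing,
    )


def run_eve_r(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    tree: Phylogeny,
    p_div: float = 0.05,
    p_change: float = 0.05,
    change_in: str = "any",
) -> pd.DataFrame:
    """EVE-R: ambient-divergence candidates filtered for a stimulus change.

    Step 1 runs the EVE divergence test on control samples only and keeps
    genes called ``divergence`` with ``p < p_div``.  Step 2 applies, per
    species, a two-sided Welch t-test of control vs treatment; a gene is
    ``thermally_induced`` if the change p-value clears ``p_change`` in at
    least one species (``change_in="all"`` requires every species).  Final
    candidates are the step-1 genes that are thermally induced; all
    intermediate columns are returned for every gene.
    """
    if change_in not in ("any", "all"):
        raise ValueError("change_in must be 'any' or 'all'")
    ctrl, trt = _split_conditions(meta)
    layout = SampleLayout.from_metadata(ctrl)
    result = eve.divergence_test(
        expr[list(ctrl["sample_id"])], tree, layout, p_threshold=p_div
    )
    out = result[["beta_i", "beta_shared", "lrt", "pvalue", "qvalue",
                  "call", "converged", "degenerate"]].copy()
    out = out.rename(columns={"pvalue": "eve_pvalue", "qvalue": "eve_qvalue"})
    ambient_divergent = (out["call"] == "divergence") & (out["eve_pvalue"] < p_div)
    out["ambient_divergent"] = ambient_divergent

    species = list(dict.fromkeys(meta["species"]))
    change_cols = []
    for sp in species:
        c_ids = ctrl.loc[ctrl["species"] == sp, "sample_id"].tolist()
        t_ids = trt.loc[trt["species"] == sp, "sample_id"].tolist()
        col = f"change_p_{sp}"
        change_cols.append(col)
        if len(c_ids) < 2 or len(t_ids) < 2:
            warnings.warn(
                f"species {sp!r} has < 2 replicates in a condition; "
                "its change test is skipped", RuntimeWarning,
            )
            out[col] = np.nan
            continue
        pvals = np.empty(len(expr))
        C = expr[c_ids].to_numpy()
        T = expr[t_ids].to_numpy()
        for i in range(len(expr)):
            pvals[i] = welch_t_test(C[i], T[i])[1]
        out[col] = pvals

    change = out[change_cols]
    if change_in == "any":
        induced = (change < p_change).any(axis=1)
    else:
        induced = (change < p_change).all(axis=1) & change.notna().all(axis=1)
    out["thermally_induced"] = induced
    out["candidate"] = ambient_divergent & induced
    return out


def run_everest(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    tree: Phylogeny,
    sign: str = "treatment_minus_control",
    pairing: str = "by_replicate_label",
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """EVEReSt: the EVE divergence test on per-species paired responses.

    Response columns (one per complete control/treatment pair) are treated
    as the individuals of the phylogenetic ANOVA, so a gene is called
    divergent when its *response* to the stimulus differs between lineages
    beyond what the shared within/between variance ratio predicts.  The
    sign and pairing conventions are recorded in ``result.attrs``.
    """
    resp = compute_response(expr, meta, sign=sign, pairing=pairing)
    missing = set(tree.tips) - set(resp.species)
    if missing:
        raise ValueError(
            f"no response columns for tree species: {sorted(missing)}"
        )
    result = eve.divergence_test(
        resp.values, tree, resp.layout, p_threshold=p_threshold
    )
    result.attrs["sign"] = sign
    result.attrs["pairing"] = pairing
    return result
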
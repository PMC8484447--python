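"""Holobiont metabolic fingerprints and redundancy.

The Quantitative Metabolic Fingerprint (QMF) summarises, for each
holobiont member (host, symbiont, bacteria), how its expressed
KEGG-annotated transcripts distribute over KEGG pathways and how that
distribution shifts between the ambient and heat conditions.  Metabolic
redundancy is assessed at the level of Enzyme Commission (EC) numbers:
each EC is multipartite (carried by all three members), bipartite
(exactly two) or unique (one), and the expression falling into each
category is totalled per member and condition.

Multi-valued annotation fields (a transcript in several pathways or with
several ECs) are counted in every pathway / EC they name; no fractional
splitting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QMFResult",
    "ReactionPartition",
    "filter_expressed",
    "compute_qmf",
    "capability_shares",
    "classify_reactions",
    "category_expression",
]

MEMBERS = ("host", "symbiont", "bacteria")
CATEGORY_BY_SIZE = {1: "unique", 2: "bipartite", 3: "multipartite"}
_KNOWN_CONDITIONS = ("ambient", "heat", "control", "treatment")


def _sample_conditions(
    tpm: pd.DataFrame, conditions: dict[str, str] | None
) -> dict[str, str]:
    """Condition label per TPM column, inferred from 'cond_rep' names."""
    if conditions is not None:
        missing = [c for c in tpm.columns if c not in conditions]
        if missing:
            raise ValueError(f"columns without condition labels: {missing}")
        return dict(conditions)
    out = {}
    for c in tpm.columns:
        prefix = str(c).split("_")[0]
        if prefix not in _KNOWN_CONDITIONS:
            raise ValueError(
                f"cannot infer condition for column {c!r}; pass an explicit "
                "column -> condition mapping"
            )
        out[c] = prefix
    return out


def _split_multi(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    s = str(value).strip()
    if not s or s == "NA":
        return []
    return [p for p in s.split(";") if p]


def filter_expressed(
    tpm: pd.DataFrame,
    min_tpm: float = 10.0,
    min_samples: int = 2,
    conditions: dict[str, str] | None = None,
) -> list[str]:
    """Transcripts with TPM >= ``min_tpm`` in >= ``min_samples`` samples.

    Control and treatment samples are counted together ("and/or"), so a
    transcript expressed only under heat still qualifies.  Returns kept
    transcript ids in matrix order.
    """
    _sample_conditions(tpm, conditions)  # validates labelling
    hits = (tpm.to_numpy(dtype=float) >= min_tpm).sum(axis=1)
    return [t for t, h in zip(tpm.index, hits) if h >= min_samples]


@dataclass
class QMFResult:
    """Per-member pathway fingerprints and condition fold changes.

    ``proportions``: rows (member, pathway, condition, value).
    ``fold_change``: rows (member, pathway) with both condition values,
    their ratio (treated/baseline), its log2 and an ``infinite`` flag for
    pathways silent at baseline but expressed after treatment.
    """

    proportions: pd.DataFrame
    fold_change: pd.DataFrame
    statistic: str
    denominator: str


def compute_qmf(
    tpm: pd.DataFrame,
    annotation: pd.DataFrame,
    statistic: str = "sum",
    denominator: str = "member_kegg_total",
    conditions: dict[str, str] | None = None,
    kept: list[str] | None = None,
    min_tpm: float = 10.0,
    min_samples: int = 2,
    condition_pair: tuple[str, str] | None = None,
) -> QMFResult:
    """Quantitative Metabolic Fingerprint per holobiont member.

    A transcript's condition value is its mean TPM over that condition's
    replicates.  The fingerprint entry for (member, pathway, condition) is
    the ``statistic`` ("sum" or "median") of those values over the
    member's kept transcripts annotated to the pathway, divided by the
    ``denominator``: ``member_kegg_total`` (the member's total over all
    its pathway-annotated kept transcripts in that condition — fingerprint
    rows then sum to one per member and condition under the sum statistic)
    or ``library_total`` (all expression in the condition's libraries).
    Fold changes compare the treated condition to the baseline condition.
    """
    if statistic not in ("sum", "median"):
        raise ValueError("statistic must be 'sum' or 'median'")
    if denominator not in ("member_kegg_total", "library_total"):
        raise ValueError(
            "denominator must be 'member_kegg_total' or 'library_total'"
        )
    cond_of = _sample_conditions(tpm, conditions)
    conds = list(dict.fromkeys(cond_of.values()))
    if condition_pair is None:
        if len(conds) != 2:
            raise ValueError(
                f"need exactly 2 conditions for fold changes, got {conds}"
            )
        order = {c: i for i, c in enumerate(_KNOWN_CONDITIONS)}
        baseline, treated = sorted(conds, key=lambda c: order.get(c, 99))
    else:
        baseline, treated = condition_pair
    if kept is None:
        kept = filter_expressed(tpm, min_tpm, min_samples, conditions)
    kept_set = set(kept)

    ann = annotation.set_index("transcript_id") \
        if "transcript_id" in annotation.columns else annotation
    # per-condition mean TPM per transcript
    cond_mean = pd.DataFrame({
        c: tpm[[s for s in tpm.columns if cond_of[s] == c]].mean(axis=1)
        for c in (baseline, treated)
    })

    # long table: one row per kept (transcript, pathway)
    rows = []
    for t in tpm.index:
        if t not in kept_set or t not in ann.index:
            continue
        member = ann.at[t, "member"]
        for pw in _split_multi(ann.at[t, "pathway"]):
            rows.append((t, member, pw))
    long = pd.DataFrame(rows, columns=["transcript_id", "member", "pathway"])

    prop_rows = []
    for cond in (baseline, treated):
        means = cond_mean[cond]
        if denominator == "library_total":
            denom_all = float(
                tpm[[s for s in tpm.columns if cond_of[s] == cond]]
                .mean(axis=1).sum()
            )
        for member, sub in long.groupby("member", sort=True):
            if denominator == "member_kegg_total":
                # total over pathway assignments, so a transcript in k
                # pathways weighs k times in numerators and denominator
                # alike and the fingerprint rows sum to one
                denom = float(means.loc[sub["transcript_id"]].sum())
                if denom <= 0:
                    raise ValueError(
                        f"zero total expression for member {member!r} in "
                        f"condition {cond!r}"
                    )
            else:
                denom = denom_all
                if denom <= 0:
                    raise ValueError(
                        f"zero library total in condition {cond!r}"
                    )
            for pw, ptab in sub.groupby("pathway", sort=True):
                vals = means.loc[ptab["transcript_id"]].to_numpy()
                num = float(vals.sum()) if statistic == "sum" \
                    else float(np.median(vals))
                prop_rows.append(
                    {"member": member, "pathway": pw, "condition": cond,
                     "value": num / denom}
                )
    proportions = pd.DataFrame(prop_rows)

    wide = proportions.pivot_table(
        index=["member", "pathway"], columns="condition", values="value",
        fill_value=0.0,
    ).reset_index()
    for c in (baseline, treated):
        if c not in wide.columns:
            wide[c] = 0.0
    # drop pathways absent in a member under both conditions
    wide = wide[(wide[baseline] > 0) | (wide[treated] > 0)].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = wide[treated].to_numpy() / wide[baseline].to_numpy()
    infinite = (wide[baseline].to_numpy() == 0) & (wide[treated].to_numpy() > 0)
    fc = np.where(infinite, np.inf, fc)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(fc, where=np.isfinite(fc) & (fc > 0),
                         out=np.full_like(fc, np.nan))
    log2fc = np.where(infinite, np.inf, log2fc)
    fold = wide.rename(columns={baseline: "baseline_value",
                                treated: "treated_value"})
    fold["fold_change"] = fc
    fold["log2_fold_change"] = log2fc
    fold["infinite"] = infinite
    fold.attrs["baseline"] = baseline
    fold.attrs["treated"] = treated
    return QMFResult(
        proportions=proportions, fold_change=fold,
        statistic=statistic, denominator=denominator,
    )


def capability_shares(
    annotation: pd.DataFrame, kept_transcripts: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Transcript-count capability shares per member and pathway.

    Counts distinct kept transcripts per (member, pathway) as proportions
    of the holobiont's total kept pathway-annotated transcripts.  A
    transcript in several pathways contributes to each pathway count but
    only once to its member's marginal share.
    """
    ann = annotation.set_index("transcript_id") \
        if "transcript_id" in annotation.columns else annotation
    kept = [t for t in kept_transcripts if t in ann.index]
    annotated = [t for t in kept if _split_multi(ann.at[t, "pathway"])]
    total = len(annotated)
    if total == 0:
        return (pd.DataFrame(columns=["member", "pathway", "count", "share"]),
                pd.Series(dtype=float, name="member_share"))
    counts: dict[tuple[str, str], int] = {}
    member_counts: dict[str, int] = {}
    for t in annotated:
        member = ann.at[t, "member"]
        member_counts[member] = member_counts.get(member, 0) + 1
        for pw in _split_multi(ann.at[t, "pathway"]):
            counts[(member, pw)] = counts.get((member, pw), 0) + 1
    table = pd.DataFrame(
        [{"member": m, "pathway": p, "count": c, "share": c / total}
         for (m, p), c in sorted(counts.items())]
    )
    member_share = pd.Series(
        {m: c / total for m, c in sorted(member_counts.items())},
        name="member_share",
    )
    return table, member_share


@dataclass
class ReactionPartition:
    """EC numbers partitioned by how many members carry them.

    ``table`` rows: ec, category (multipartite/bipartite/unique), carriers
    (sorted tuple of members), pair (for bipartite, the member pair label).
    ``unexpressed`` lists ECs annotated but carried by no member under the
    presence rule in force.
    """

    table: pd.DataFrame
    unexpressed: list[str]

    def counts(self) -> dict[str, int]:
        if self.table.empty:
            return {c: 0 for c in CATEGORY_BY_SIZE.values()}
        vc = self.table["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CATEGORY_BY_SIZE.values()}


def classify_reactions(
    annotation: pd.DataFrame,
    kept_transcripts: list[str] | None = None,
) -> ReactionPartition:
    """Partition annotated EC reactions into multipartite/bipartite/unique.

    A member carries an EC when at least one of its transcripts (optionally
    restricted to ``kept_transcripts``, the expressed-only rule) is
    annotated with it.  The category is determined solely by the carrier
    set size; ECs with an empty carrier set under a restricted rule are
    reported separately, not classified.
    """
    ann = annotation.set_index("transcript_id") \
        if "transcript_id" in annotation.columns else annotation
    carriers: dict[str, set[str]] = {}
    all_ecs: set[str] = set()
    keep = set(kept_transcripts) if kept_transcripts is not None else None
    for t in ann.index:
        ecs = _split_multi(ann.at[t, "ec"])
        all_ecs.update(ecs)
        if keep is not None and t not in keep:
            continue
        member = ann.at[t, "member"]
        for ec in ecs:
            carriers.setdefault(ec, set()).add(member)
    rows = []
    for ec in sorted(carriers):
        cset = tuple(sorted(carriers[ec]))
        cat = CATEGORY_BY_SIZE[len(cset)]
        rows.append(
            {"ec": ec, "category": cat, "carriers": cset,
             "pair": "-".join(cset) if len(cset) == 2 else ""}
        )
    table = pd.DataFrame(rows, columns=["ec", "category", "carriers", "pair"])
    unexpressed = sorted(all_ecs - set(carriers))
    return ReactionPartition(table=table, unexpressed=unexpressed)


def category_expression(
    tpm: pd.DataFrame,
    partition: ReactionPartition,
    annotation: pd.DataFrame,
    conditions: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Total TPM per (redundancy category, member, condition).

    Sums the per-condition mean TPM of every transcript whose EC
    annotation falls in a category; a transcript whose ECs span several
    categories contributes to each and is flagged ``multi_category``.
    """
    cond_of = _sample_conditions(tpm, conditions)
    ann = annotation.set_index("transcript_id") \
        if "transcript_id" in annotation.columns else annotation
    cat_of = ({} if partition.table.empty
              else dict(zip(partition.table["ec"], partition.table["category"])))
    conds = list(dict.fromkeys(cond_of.values()))
    cond_mean = pd.DataFrame({
        c: tpm[[s for s in tpm.columns if cond_of[s] == c]].mean(axis=1)
        for c in conds
    })
    totals: dict[tuple[str, str, str], float] = {}
    multi_flagged: list[str] = []
    for t in tpm.index:
        if t not in ann.index:
            continue
        cats = {cat_of[ec] for ec in _split_multi(ann.at[t, "ec"])
                if ec in cat_of}
        if not cats:
            continue
        if len(cats) > 1:
            multi_flagged.append(t)
        member = ann.at[t, "member"]
        for cat in cats:
            for c in conds:
                key = (cat, member, c)
                totals[key] = totals.get(key, 0.0) + float(cond_mean.at[t, c])
    out = pd.DataFrame(
        [{"category": k[0], "member": k[1], "condition": k[2], "tpm_total": v}
         for k, v in sorted(totals.items())],
        columns=["category", "member", "condition", "tpm_total"],
    )
    out.attrs["multi_category_transcripts"] = multi_flagged
    return out
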
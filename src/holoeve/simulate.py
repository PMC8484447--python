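"""Synthetic holobiont datasets with known ground truth.

Emulates the design of a three-species thermal-stress experiment: three
taxa on a ((A,B),C) tree, two conditions (control / treatment) with three
paired replicates per species, ortholog expression with OU-phylogenetic
covariance across species, and member-labelled transcript annotation
tables with TPM matrices for the metabolism analyses.

Every planted signal (lineage-specific optimum shift, inflated
within-species variability, treatment response) is recorded gene by gene
in a ground-truth table so that downstream tests can score recovery.

Expression is simulated directly on the continuous analysis scale (the
scale the OU model operates on), not as read counts; species means are
drawn from the OU stationary distribution; divergence is planted as a
post-hoc optimum shift on one lineage, which leaves the marginal
covariance identical to the null while making the ground truth explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import eve
from .eve import OUGeneParams, SampleLayout
from .phylogeny import Phylogeny, THREE_TAXON_NEWICK

__all__ = [
    "SimulationConfig",
    "SpeciesPhysioEffect",
    "make_tree",
    "simulate_expression",
    "simulate_annotation",
    "simulate_physiology",
]

GENE_CLASSES = ("null", "divergence", "diversity", "responsive")
CONDITIONS = ("control", "treatment")


@dataclass
class SimulationConfig:
    """Study design and effect sizes for the expression simulator.

    Parameter ranges are sampled per gene (uniformly); ``shared_beta`` is a
    single value common to all genes, matching the shared-``beta`` null of
    the divergence test.  Effect sizes are expressed in units of the
    gene's stationary SD ``sqrt(sigma2 / (2 alpha))``.
    """

    tree_spec: str = "three_taxon"
    n_genes: int = 500
    n_replicates_per_condition: int = 3
    gene_class_proportions: dict = field(
        default_factory=lambda: {
            "null": 0.7, "divergence": 0.1, "diversity": 0.1, "responsive": 0.1,
        }
    )
    theta_range: tuple[float, float] = (3.0, 8.0)
    sigma2_range: tuple[float, float] = (0.5, 2.0)
    alpha_range: tuple[float, float] = (0.25, 1.0)
    shared_beta: float = 1.0
    divergence_effect: float = 3.0
    diversity_beta_factor: float = 8.0
    response_effect: float = 3.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.gene_class_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(
                f"gene_class_proportions must sum to 1, got {total}"
            )
        unknown = set(self.gene_class_proportions) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates_per_condition < 1:
            raise ValueError("need at least one replicate per condition")
        for name, (lo, hi) in (
            ("sigma2_range", self.sigma2_range),
            ("alpha_range", self.alpha_range),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")
        if self.shared_beta < 0:
            raise ValueError("shared_beta must be >= 0")
        if self.diversity_beta_factor <= 1:
            raise ValueError("diversity_beta_factor must be > 1")


def make_tree(tree_spec: str) -> Phylogeny:
    """Build the species tree from a newick string or the preset name.

    ``"three_taxon"`` returns ((A:1,B:1):1,C:2): sister species A and B at
    patristic distance 2, outgroup C at distance 4 from both.
    """
    if tree_spec == "three_taxon":
        return Phylogeny.from_newick(THREE_TAXON_NEWICK)
    return Phylogeny.from_newick(tree_spec)


def _class_counts(props: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Largest-remainder apportionment of n genes to classes, shuffled."""
    classes = [c for c in GENE_CLASSES if props.get(c, 0) > 0]
    exact = np.array([props[c] * n for c in classes])
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)
    return labels


def simulate_expression(
    config: SimulationConfig, tree: Phylogeny | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw an ortholog expression matrix with planted gene classes.

    Returns ``(expression, metadata, ground_truth)``.  Expression is a
    genes x samples DataFrame; metadata has one row per sample
    (sample_id, species, condition, replicate); ground truth records each
    gene's class, true OU parameters and any planted effect.  The same
    replicate label in control and treatment denotes a paired colony.
    """
    if tree is None:
        tree = make_tree(config.tree_spec)
    rng = np.random.default_rng(config.seed)
    species = list(tree.tips)
    reps = config.n_replicates_per_condition

    sample_ids, meta_rows = [], []
    for sp in species:
        for cond in CONDITIONS:
            for r in range(1, reps + 1):
                sid = f"{sp}_{cond}_r{r}"
                sample_ids.append(sid)
                meta_rows.append(
                    {"sample_id": sid, "species": sp,
                     "condition": cond, "replicate": f"r{r}"}
                )
    meta = pd.DataFrame(meta_rows)
    layout = SampleLayout(
        species=tuple(meta["species"]), sample_ids=tuple(sample_ids)
    )

    labels = _class_counts(config.gene_class_proportions, config.n_genes, rng)
    expr = np.empty((config.n_genes, layout.n))
    truth_rows = []
    treat_mask = (meta["condition"] == "treatment").to_numpy()

    for g in range(config.n_genes):
        cls = labels[g]
        theta = rng.uniform(*config.theta_range)
        sigma2 = rng.uniform(*config.sigma2_range)
        alpha = rng.uniform(*config.alpha_range)
        beta = config.shared_beta
        if cls == "diversity":
            beta = beta * config.diversity_beta_factor
        if not np.isfinite([theta, sigma2, alpha, beta]).all():
            raise ValueError(f"non-finite parameter draw for gene index {g}")
        params = OUGeneParams(theta=theta, sigma2=sigma2, alpha=alpha,
                              beta=max(beta, 1e-12))
        cov = eve.build_covariance(tree, params, layout)
        L = np.linalg.cholesky(cov)
        y = theta + L @ rng.standard_normal(layout.n)

        shifted_lineage = ""
        responsive_species = ""
        sd = params.stationary_sd
        if cls == "divergence":
            shifted_lineage = species[rng.integers(len(species))]
            on = (meta["species"] == shifted_lineage).to_numpy()
            y = y + config.divergence_effect * sd * on
        elif cls == "responsive":
            responsive_species = species[rng.integers(len(species))]
            on = (meta["species"] == responsive_species).to_numpy() & treat_mask
            y = y + config.response_effect * sd * on
        expr[g] = y
        truth_rows.append(
            {"gene_id": f"g{g:05d}", "gene_class": cls,
             "theta": theta, "sigma2": sigma2, "alpha": alpha, "beta": beta,
             "shifted_lineage": shifted_lineage,
             "responsive_species": responsive_species,
             "divergence_effect": config.divergence_effect if cls == "divergence" else 0.0,
             "response_effect": config.response_effect if cls == "responsive" else 0.0}
        )

    gene_ids = [r["gene_id"] for r in truth_rows]
    expr_df = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                           columns=sample_ids)
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return expr_df, meta, truth


# ----------------------------------------------------------------------
# Annotation / TPM
# ----------------------------------------------------------------------
MEMBERS = ("host", "symbiont", "bacteria")


def simulate_annotation(
    n_transcripts_per_member: int,
    pathway_catalog: list[str],
    ec_catalog: list[str],
    overlap_design: dict[str, tuple[str, ...]],
    seed: int = 0,
    n_samples_per_condition: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Member-labelled transcript annotation with a TPM matrix.

    ``overlap_design`` maps each EC number to the set of holobiont members
    carrying it, so the true multipartite/bipartite/unique partition is
    known by construction.  Each transcript is assigned exactly one member,
    one KO, and 1-2 pathways; TPM columns (``ambient_r*``/``heat_r*``) are
    normalised to one million per sample.
    """
    if not pathway_catalog or not ec_catalog:
        raise ValueError("pathway and EC catalogs must be non-empty")
    if n_transcripts_per_member < 1:
        raise ValueError("need >= 1 transcript per member")
    bad = {ec: m for ec, m in overlap_design.items()
           if not set(m) <= set(MEMBERS) or not m}
    if bad:
        raise ValueError(f"overlap_design has invalid member sets: {bad}")
    rng = np.random.default_rng(seed)

    rows = []
    member_transcripts: dict[str, list[str]] = {m: [] for m in MEMBERS}
    tid = 0
    for member in MEMBERS:
        for _ in range(n_transcripts_per_member):
            t = f"t{tid:05d}"
            tid += 1
            member_transcripts[member].append(t)
            n_pw = int(rng.integers(1, min(2, len(pathway_catalog)) + 1))
            pws = rng.choice(pathway_catalog, size=n_pw, replace=False)
            rows.append(
                {"transcript_id": t, "member": member,
                 "ko": f"K{rng.integers(0, 99999):05d}",
                 "pathway": ";".join(sorted(pws)), "ec": ""}
            )
    ann = pd.DataFrame(rows).set_index("transcript_id")

    # plant each designed EC on >= 1 transcript of every carrier member
    ec_assign: dict[str, set[str]] = {t: set() for t in ann.index}
    for ec in ec_catalog:
        carriers = overlap_design.get(ec, ())
        for member in carriers:
            pool = member_transcripts[member]
            n_pick = int(rng.integers(1, min(2, len(pool)) + 1))
            for t in rng.choice(pool, size=n_pick, replace=False):
                ec_assign[t].add(ec)
    ann["ec"] = [";".join(sorted(ec_assign[t])) for t in ann.index]

    samples = [f"ambient_r{i}" for i in range(1, n_samples_per_condition + 1)]
    samples += [f"heat_r{i}" for i in range(1, n_samples_per_condition + 1)]
    raw = rng.lognormal(mean=2.0, sigma=1.2, size=(len(ann), len(samples)))
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(tpm, index=ann.index.copy(), columns=samples)
    return ann.reset_index(), tpm_df


# ----------------------------------------------------------------------
# Physiology
# ----------------------------------------------------------------------
@dataclass
class SpeciesPhysioEffect:
    """Control means and treatment shifts for one species' optical traits.

    ``r675`` (reflectance at 675 nm) and ``fv_fm`` shifts are additive;
    the symbiont-density shift is a fraction of the control mean (e.g.
    ``-0.5`` halves the treated density).
    """

    r675_control: float = 0.3
    r675_shift: float = 0.0
    density_control: float = 1e10
    density_shift_frac: float = 0.0
    fv_fm_control: float = 0.6
    fv_fm_shift: float = 0.0


def simulate_physiology(
    seed: int,
    effects: dict[str, SpeciesPhysioEffect],
    n_fragments: int = 5,
    noise_r675: float = 0.02,
    noise_density_frac: float = 0.05,
    noise_fv_fm: float = 0.02,
) -> pd.DataFrame:
    """Per-fragment physiology records (R675, symbiont density, Fv/Fm).

    Values outside the physical domains (R675 in (0, 1], Fv/Fm in [0, 1],
    density > 0) are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    clipped = False
    for sp, eff in effects.items():
        for cond in CONDITIONS:
            treat = cond == "treatment"
            mu_r = eff.r675_control + (eff.r675_shift if treat else 0.0)
            mu_d = eff.density_control * (
                1.0 + (eff.density_shift_frac if treat else 0.0)
            )
            mu_f = eff.fv_fm_control + (eff.fv_fm_shift if treat else 0.0)
            for i in range(1, n_fragments + 1):
                r = mu_r + rng.normal(0.0, noise_r675)
                d = mu_d * (1.0 + rng.normal(0.0, noise_density_frac))
                f = mu_f + rng.normal(0.0, noise_fv_fm)
                if not (0.0 < r <= 1.0):
                    r = min(max(r, 1e-6), 1.0)
                    clipped = True
                if d <= 0:
                    d = 1e-6
                    clipped = True
                if not (0.0 <= f <= 1.0):
                    f = min(max(f, 0.0), 1.0)
                    clipped = True
                rows.append(
                    {"species": sp, "fragment_id": f"{sp}_f{i}",
                     "condition": cond, "r675": r, "density": d, "fv_fm": f}
                )
    if clipped:
        warnings.warn(
            "some simulated physiology values were clipped to their "
            "physical domain", RuntimeWarning,
        )
    return pd.DataFrame(rows)
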
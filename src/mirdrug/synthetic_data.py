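"""Synthetic cell-line panels with planted effects and recorded ground truth.

The generator emulates the statistical structure the analysis assumes, at the
study's scale by default: 36 cell lines, 411 miRNAs on the log10 intensity
scale, 34 drugs whose -log10 IC50 is a linear function of miRNA expression
and/or subtype plus Gaussian noise, right-censored at the maximum tested
concentration, and an mRNA matrix in which designated gene sets co-vary with a
designated miRNA.

Planted structure (all recorded in :class:`GroundTruth`):

* *direct* associations: -log10 IC50 gains a term beta * miRNA, with beta set
  from the target population Pearson correlation r via
  beta = sign * (noise_sd / sigma_feature) * r / sqrt(1 - r^2);
* *confounded* associations: the miRNA gains a subtype shift and the same
  subtype shifts the drug response, with no direct miRNA term -- the observed
  correlation is entirely an echo of subtype;
* *pathway signal*: each planted gene set's genes equal
  loading * (target miRNA row) + unit Gaussian noise; all other genes are noise.

Censoring is specified as the *fraction* of lines recorded at the maximum
tested concentration: the drug's ``max_conc`` is set to the
(1 - censor_quantile) quantile of the latent IC50s and everything above it is
truncated there.  That puts a drug on the Spearman branch near 0, the 2-step
branch at intermediate fractions and the Mann-Whitney branch above ~0.75.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .association import AssociationResult
from .confounding import MultivariateResult
from .core_io import (
    SUBTYPES,
    DrugResponseProfile,
    ExpressionMatrix,
    GeneSetCollection,
    Scale,
    SubtypeLabels,
    write_drug_response,
    write_expression_matrix,
    write_gene_sets,
    write_subtype_labels,
)


@dataclass(frozen=True)
class PlantedAssoc:
    mirna: str
    drug: str
    target_rho: float  # population Pearson correlation on the -log10 scale
    direction: int  # +1 sensitivity, -1 resistance


@dataclass(frozen=True)
class ConfoundedAssoc:
    mirna: str
    drug: str
    subtype: str
    mirna_shift_sd: float = 4.0  # subtype shift on the miRNA, in feature SDs
    drug_shift_sd: float = 4.0  # subtype shift on -log10 IC50, in noise SDs


@dataclass(frozen=True)
class PlantedSet:
    set_name: str
    target_mirna: str
    loading: float = 1.0
    n_genes: int = 20


def _default_planted() -> tuple[PlantedAssoc, ...]:
    return tuple(
        PlantedAssoc(
            mirna=f"miR-{i + 1:04d}",
            drug=f"drug-{i + 1:02d}",
            target_rho=0.75,
            direction=1 if i % 2 == 0 else -1,
        )
        for i in range(10)
    )


def _default_confounded() -> tuple[ConfoundedAssoc, ...]:
    return (
        ConfoundedAssoc(mirna="miR-0011", drug="drug-11", subtype="basal"),
        ConfoundedAssoc(mirna="miR-0012", drug="drug-12", subtype="luminal"),
        ConfoundedAssoc(mirna="miR-0013", drug="drug-13", subtype="basal"),
    )


def _default_censoring(n_drugs: int) -> tuple[float, ...]:
    # 20 "linear" drugs, 8 intermediate (2-step), the rest heavily censored
    out = []
    for i in range(n_drugs):
        if i < 20:
            out.append(0.05)
        elif i < 28:
            out.append(0.40)
        else:
            out.append(0.85)
    return tuple(out)


def _default_sets() -> tuple[PlantedSet, ...]:
    return (
        PlantedSet("SET_planted_1", "miR-0001", loading=1.0),
        PlantedSet("SET_planted_2", "miR-0002", loading=1.0),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    n_samples: int = 36
    n_mirnas: int = 411
    n_drugs: int = 34
    subtype_probs: tuple[float, float, float] = (0.50, 0.35, 0.15)  # basal, luminal, normal-like
    planted_assocs: tuple[PlantedAssoc, ...] = field(default_factory=_default_planted)
    confounded_assocs: tuple[ConfoundedAssoc, ...] = field(default_factory=_default_confounded)
    censor_quantile: tuple[float, ...] | None = None  # per drug; None -> default profile
    noise_sd: float = 0.4  # decades, on -log10 IC50
    n_genes: int = 500
    planted_sets: tuple[PlantedSet, ...] = field(default_factory=_default_sets)
    n_null_sets: int = 8
    genes_per_null_set: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.subtype_probs, dtype=float)
        if len(probs) != 3 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("subtype_probs must be 3 nonnegative numbers summing to 1")
        cq = self.censoring_profile()
        if len(cq) != self.n_drugs or any(not 0 <= c < 1 for c in cq):
            raise ValueError("censor_quantile must give one value in [0, 1) per drug")
        mirnas = set(self.mirna_ids())
        drugs = set(self.drug_ids())
        for a in list(self.planted_assocs) + list(self.confounded_assocs):
            if a.mirna not in mirnas or a.drug not in drugs:
                raise ValueError(f"planted index out of range: {a}")
        for s in self.planted_sets:
            if s.target_mirna not in mirnas:
                raise ValueError(f"planted set targets unknown miRNA: {s}")

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_mirnas)]

    def drug_ids(self) -> list[str]:
        return [f"drug-{i + 1:02d}" for i in range(self.n_drugs)]

    def sample_ids(self) -> list[str]:
        return [f"CL-{i + 1:02d}" for i in range(self.n_samples)]

    def censoring_profile(self) -> tuple[float, ...]:
        return (
            self.censor_quantile
            if self.censor_quantile is not None
            else _default_censoring(self.n_drugs)
        )


@dataclass(frozen=True)
class GroundTruth:
    """Which (miRNA, drug) pairs the generating process makes dependent.

    ``subtype_linked_pairs`` covers the cross-talk the confounded constructs
    create: any subtype-shifted miRNA is dependent on any subtype-shifted
    drug, because the three subtype indicators are mutually (negatively)
    correlated.  Pairs outside all three tuples are genuinely null.
    """

    planted_pairs: tuple[tuple[str, str], ...]  # direct (miRNA, drug)
    confounded_pairs: tuple[tuple[str, str, str], ...]  # (miRNA, drug, subtype)
    subtype_linked_pairs: tuple[tuple[str, str], ...]  # all cross-talk pairs
    pathway_pairs: tuple[tuple[str, str], ...]  # (miRNA, set_name)

    def non_null_pairs(self) -> set[tuple[str, str]]:
        return (
            set(self.planted_pairs)
            | {(m, d) for m, d, _ in self.confounded_pairs}
            | set(self.subtype_linked_pairs)
        )

    def is_true_pair(self, mirna: str, drug: str) -> bool:
        return (mirna, drug) in self.non_null_pairs()


@dataclass(frozen=True)
class SyntheticPanel:
    mirna: ExpressionMatrix  # LOG10 scale
    drugs: tuple[DrugResponseProfile, ...]
    subtypes: SubtypeLabels
    mrna: ExpressionMatrix  # LOG10 scale
    gene_sets: GeneSetCollection
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the panel in the TSV/GMT formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna": outdir / "mirna_log10.tsv",
            "drugs": outdir / "ic50.tsv",
            "subtypes": outdir / "subtypes.tsv",
            "mrna": outdir / "mrna_log10.tsv",
            "gene_sets": outdir / "gene_sets.gmt",
        }
        write_expression_matrix(self.mirna, paths["mirna"])
        write_drug_response(self.drugs, paths["drugs"])
        write_subtype_labels(self.subtypes, paths["subtypes"])
        write_expression_matrix(self.mrna, paths["mrna"])
        write_gene_sets(self.gene_sets, paths["gene_sets"])
        return paths


def generate_panel(cfg: SyntheticConfig) -> SyntheticPanel:
    """Draw one full panel (miRNA, drugs, subtypes, mRNA, gene sets) from ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n, ids = cfg.n_samples, cfg.sample_ids()
    mirna_ids, drug_ids = cfg.mirna_ids(), cfg.drug_ids()
    mirna_index = {m: i for i, m in enumerate(mirna_ids)}

    labels = tuple(rng.choice(SUBTYPES, size=n, p=cfg.subtype_probs))
    subtypes = SubtypeLabels(sample_ids=tuple(ids), labels=labels)

    # log10 miRNA expression: per-feature mean and spread, plus subtype shifts
    mu = rng.uniform(1.0, 3.0, size=cfg.n_mirnas)
    sigma = rng.uniform(0.2, 0.5, size=cfg.n_mirnas)
    X = mu[:, None] + sigma[:, None] * rng.standard_normal((cfg.n_mirnas, n))
    for c in cfg.confounded_assocs:
        i = mirna_index[c.mirna]
        X[i] += c.mirna_shift_sd * sigma[i] * subtypes.indicator(c.subtype, ids)
    mirna = ExpressionMatrix(tuple(mirna_ids), tuple(ids), X, Scale.LOG10)

    planted_by_drug: dict[str, list[PlantedAssoc]] = {}
    for a in cfg.planted_assocs:
        planted_by_drug.setdefault(a.drug, []).append(a)
    confounded_by_drug: dict[str, list[ConfoundedAssoc]] = {}
    for c in cfg.confounded_assocs:
        confounded_by_drug.setdefault(c.drug, []).append(c)

    drugs = []
    censoring = cfg.censoring_profile()
    for d, drug in enumerate(drug_ids):
        latent = rng.uniform(5.0, 7.0) + cfg.noise_sd * rng.standard_normal(n)
        for a in planted_by_drug.get(drug, []):
            i = mirna_index[a.mirna]
            beta = (
                a.direction
                * (cfg.noise_sd / sigma[i])
                * a.target_rho
                / np.sqrt(1 - a.target_rho**2)
            )
            latent = latent + beta * (X[i] - mu[i])
        for c in confounded_by_drug.get(drug, []):
            # note the sign: a positive shift on -log10 IC50 means sensitivity
            latent = latent + c.drug_shift_sd * cfg.noise_sd * subtypes.indicator(
                c.subtype, ids
            )
        ic50 = 10.0 ** (-latent)
        cq = censoring[d]
        if cq > 0:
            max_conc = float(np.quantile(ic50, 1.0 - cq))
            ic50 = np.minimum(ic50, max_conc)
        else:
            max_conc = float(ic50.max() * 1.5)
        drugs.append(DrugResponseProfile(drug, tuple(ids), ic50, max_conc))

    # mRNA: planted sets track their target miRNA, everything else pure noise
    gene_ids = [f"gene-{j + 1:04d}" for j in range(cfg.n_genes)]
    G = 2.0 + rng.standard_normal((cfg.n_genes, n))
    sets: dict[str, tuple[str, ...]] = {}
    cursor = 0
    pathway_pairs = []
    for s in cfg.planted_sets:
        members = gene_ids[cursor : cursor + s.n_genes]
        if len(members) < s.n_genes:
            raise ValueError("n_genes too small for the planted sets")
        target = X[mirna_index[s.target_mirna]]
        # loading applies to the standardized target row, so it sets the
        # gene-level signal-to-noise directly (gene-miRNA correlation
        # loading / sqrt(1 + loading^2)) instead of inheriting the arbitrary
        # per-feature variance
        target_z = (target - target.mean()) / target.std()
        for gid in members:
            j = gene_ids.index(gid)
            G[j] = s.loading * target_z + rng.standard_normal(n)
        sets[s.set_name] = tuple(members)
        pathway_pairs.append((s.target_mirna, s.set_name))
        cursor += s.n_genes
    for k in range(cfg.n_null_sets):
        members = gene_ids[cursor : cursor + cfg.genes_per_null_set]
        if len(members) < cfg.genes_per_null_set:
            raise ValueError("n_genes too small for the null sets")
        sets[f"SET_null_{k + 1}"] = tuple(members)
        cursor += cfg.genes_per_null_set
    mrna = ExpressionMatrix(tuple(gene_ids), tuple(ids), G, Scale.LOG10)
    gene_sets = GeneSetCollection(sets=sets, source="synthetic")

    linked = tuple(
        (c1.mirna, c2.drug)
        for c1 in cfg.confounded_assocs
        for c2 in cfg.confounded_assocs
    )
    truth = GroundTruth(
        planted_pairs=tuple((a.mirna, a.drug) for a in cfg.planted_assocs),
        confounded_pairs=tuple((c.mirna, c.drug, c.subtype) for c in cfg.confounded_assocs),
        subtype_linked_pairs=linked,
        pathway_pairs=tuple(pathway_pairs),
    )
    return SyntheticPanel(mirna, tuple(drugs), subtypes, mrna, gene_sets, truth, cfg)


@dataclass(frozen=True)
class RecoveryReport:
    n_discoveries: int
    n_true_recovered: int
    sensitivity: float  # recovered direct pairs / planted direct pairs
    fdp: float  # discoveries that are neither direct nor confounded truth
    confounded_flagged: float | None  # tested confounded pairs flagged
    retained_direct: float | None  # tested direct pairs retained


def evaluate_recovery(
    results: Sequence[AssociationResult],
    truth: GroundTruth,
    q_threshold: float = 0.3,
    multivariate: Sequence[MultivariateResult] | None = None,
) -> RecoveryReport:
    """Score association (and optionally confounding) calls against ground truth."""
    discoveries = {
        (r.mirna, r.drug)
        for r in results
        if r.q_value is not None and r.q_value <= q_threshold
    }
    planted = set(truth.planted_pairs)
    confounded = {(m, d) for m, d, _ in truth.confounded_pairs}
    n_true = len(discoveries & planted)
    false = discoveries - truth.non_null_pairs()
    sensitivity = n_true / len(planted) if planted else float("nan")
    fdp = len(false) / len(discoveries) if discoveries else 0.0

    conf_rate = None
    ret_rate = None
    if multivariate is not None:
        by_pair = {(m.mirna, m.drug): m for m in multivariate}
        tested_conf = [by_pair[p] for p in confounded if p in by_pair]
        tested_direct = [by_pair[p] for p in planted if p in by_pair]
        if tested_conf:
            conf_rate = sum(bool(m.confounded_by) for m in tested_conf) / len(tested_conf)
        if tested_direct:
            ret_rate = sum(m.retained for m in tested_direct) / len(tested_direct)
    return RecoveryReport(
        n_discoveries=len(discoveries),
        n_true_recovered=n_true,
        sensitivity=sensitivity,
        fdp=fdp,
        confounded_flagged=conf_rate,
        retained_direct=ret_rate,
    )
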
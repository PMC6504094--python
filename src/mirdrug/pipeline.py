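"""End-to-end orchestration: classify -> associate -> q-values -> confounding ->
co-expression -> pathway screen, with tabular reports at each stage.

The report bundle mirrors the shape of the study-style result tables:

* ``analysis_methods.tsv``      -- per drug: branch and the two censoring counts;
* ``associations_all.tsv``      -- every (miRNA, drug) pair with statistic, p, q;
* ``associations_significant.tsv`` -- the q <= threshold subset (Table-1 layout);
* ``confounding.tsv``           -- per significant pair x contrast: coefficients,
  p-values, the confounded-by call and the retained flag;
* ``coexpression_<drug>.tsv``   -- rho and p matrices for drugs with >= 2 hits;
* ``pathways.tsv``              -- per retained miRNA x gene set: Q, p-values,
  BH-adjusted p, significance under the dual criterion;
* ``run_log.json``              -- seeds, parameters, per-stage row counts.

By default only Spearman-branch drugs feed the downstream stages (the branch
where "linear" IC50 profiles live); ``spearman_only_downstream=False`` lifts
the restriction.  Re-running with the same config reproduces every file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_all
from .coexpression import coexpression
from .confounding import confounding_check
from .core_io import (
    ExpressionMatrix,
    Scale,
    neglog10_ic50,
    read_drug_response,
    read_expression_matrix,
    read_gene_sets,
    read_subtype_labels,
)
from .multiple_testing import attach_q_by_branch
from .pathway import pathway_screen
from .profile_classifier import Branch, classify_profile

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mirna_path: str
    drug_path: str
    subtype_path: str
    output_dir: str
    mrna_path: str | None = None
    gene_sets_path: str | None = None
    mirna_scale: str = "log10"  # "raw" triggers the log10 transform
    q_threshold: float = 0.3
    screen_alpha: float = 0.05
    confounding_alpha: float = 0.05
    coexpression_alpha: float = 0.05
    pathway_fraction: float = 0.25
    n_perm: int = 1000
    bh_threshold: float = 0.1
    perm_threshold: float = 0.05
    seed: int = 0
    spearman_only_downstream: bool = True

    def __post_init__(self) -> None:
        for name in ("q_threshold", "screen_alpha", "confounding_alpha",
                     "coexpression_alpha", "bh_threshold", "perm_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 < self.pathway_fraction <= 0.5:
            raise ValueError("pathway_fraction must lie in (0, 0.5]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PipelineReport:
    output_dir: Path
    files: dict[str, Path]
    counts: dict[str, int] = field(default_factory=dict)


def _write_association_table(results, path: Path) -> None:
    rows = []
    for r in results:
        rows.append({
            "Drug": r.drug,
            "MiRNA": r.mirna,
            "AssociationType": r.branch.branch.value,
            "Direction": r.direction.value,
            "Statistic": r.statistic_name,
            "R_or_U": r.statistic,
            "p-value": r.p_value,
            "q-value": r.q_value if r.q_value is not None else np.nan,
            "screened": r.screened if r.screened is not None else "",
            "n": r.n_used,
        })
    columns = ["Drug", "MiRNA", "AssociationType", "Direction", "Statistic",
               "R_or_U", "p-value", "q-value", "screened", "n"]
    pd.DataFrame(rows, columns=columns).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    counts: dict[str, int] = {}

    mirna = read_expression_matrix(cfg.mirna_path, Scale(cfg.mirna_scale))
    if mirna.scale is Scale.RAW:
        from .core_io import log10_transform

        mirna = log10_transform(mirna)
    drugs = read_drug_response(cfg.drug_path)
    subtypes = read_subtype_labels(cfg.subtype_path)

    # stage 1: branch per drug
    branch_rows = []
    for p in drugs:
        b = classify_profile(p)
        branch_rows.append({
            "drug": p.drug_name, "analysis": b.branch.value,
            "n_at_max": b.n_at_max, "n_variable": b.n_variable,
        })
    files["analysis_methods"] = outdir / "analysis_methods.tsv"
    pd.DataFrame(branch_rows).to_csv(files["analysis_methods"], sep="\t", index=False)

    # stage 2: associations + q-values per branch
    results = associate_all(mirna, drugs, screen_alpha=cfg.screen_alpha)
    results = attach_q_by_branch(results, q_threshold=cfg.q_threshold)
    counts["associations"] = len(results)
    files["associations_all"] = outdir / "associations_all.tsv"
    _write_association_table(results, files["associations_all"])

    significant = [r for r in results if r.significant]
    if cfg.spearman_only_downstream:
        downstream = [r for r in significant if r.branch.branch is Branch.SPEARMAN]
    else:
        downstream = list(significant)
    counts["significant"] = len(significant)
    counts["downstream"] = len(downstream)
    files["associations_significant"] = outdir / "associations_significant.tsv"
    _write_association_table(significant, files["associations_significant"])

    # stage 3: subtype confounding on the significant pairs
    profile_by_drug = {p.drug_name: p for p in drugs}
    conf_rows = []
    retained_mirnas: list[str] = []
    multivariate = []
    for r in downstream:
        p = profile_by_drug[r.drug]
        common = [s for s in mirna.sample_ids if s in set(p.sample_ids)]
        y = neglog10_ic50(p.subset_samples(common))
        x = mirna.subset_samples(common).row(r.mirna)
        m = confounding_check(r, x, y, subtypes, common, alpha=cfg.confounding_alpha)
        multivariate.append(m)
        for subtype, fit in m.fits.items():
            row = {"Drug": m.drug, "MiRNA": m.mirna, "Contrast": f"{subtype} vs rest"}
            if fit is None:
                row.update({"evaluable": False})
            else:
                row.update({
                    "evaluable": True,
                    "beta_mirna": fit.params["mirna"],
                    "p_mirna": fit.pvalues["mirna"],
                    "beta_subtype": fit.params["subtype"],
                    "p_subtype": fit.pvalues["subtype"],
                    "n": fit.n,
                })
            row["confounded_by"] = ",".join(m.confounded_by)
            row["retained"] = m.retained
            conf_rows.append(row)
        if m.retained and m.mirna not in retained_mirnas:
            retained_mirnas.append(m.mirna)
    files["confounding"] = outdir / "confounding.tsv"
    pd.DataFrame(conf_rows).to_csv(files["confounding"], sep="\t", index=False,
                                   float_format="%.6g")
    counts["retained_mirnas"] = len(retained_mirnas)

    # stage 4: co-expression per drug with >= 2 significant miRNAs
    hits_by_drug: dict[str, list[str]] = {}
    for r in downstream:
        hits_by_drug.setdefault(r.drug, []).append(r.mirna)
    n_coex = 0
    for drug, ids in sorted(hits_by_drug.items()):
        if len(ids) < 2:
            continue
        co = coexpression(mirna, sorted(set(ids)), alpha=cfg.coexpression_alpha)
        path = outdir / f"coexpression_{drug}.tsv"
        with open(path, "w") as fh:
            fh.write("# Spearman rho\n")
            co.rho.to_csv(fh, sep="\t", float_format="%.4f")
            fh.write("# p-values\n")
            co.p.to_csv(fh, sep="\t", float_format="%.6g")
        files[f"coexpression_{drug}"] = path
        n_coex += 1
    counts["coexpression_drugs"] = n_coex

    # stage 5: pathway screen on retained miRNAs
    path_rows = []
    if cfg.mrna_path and cfg.gene_sets_path and retained_mirnas:
        mrna = read_expression_matrix(cfg.mrna_path, Scale.LOG10)
        sets = read_gene_sets(cfg.gene_sets_path)
        drug_join = {
            m: sorted({r.drug for r in downstream if r.mirna == m})
            for m in retained_mirnas
        }
        pres = pathway_screen(
            mrna, sets, mirna, retained_mirnas,
            n_perm=cfg.n_perm, seed=cfg.seed, fraction=cfg.pathway_fraction,
            bh_threshold=cfg.bh_threshold, perm_threshold=cfg.perm_threshold,
        )
        for r in pres:
            path_rows.append({
                "MiRNA": r.mirna_id, "Pathway": r.set_name, "Q": r.Q,
                "Permutation p-value": r.p_perm, "BH-adjusted p-value": r.p_bh,
                "significant": r.significant, "n_genes": r.n_genes_used,
                "Associated drugs": ", ".join(drug_join.get(r.mirna_id, [])),
            })
    files["pathways"] = outdir / "pathways.tsv"
    pd.DataFrame(
        path_rows,
        columns=["MiRNA", "Pathway", "Q", "Permutation p-value",
                 "BH-adjusted p-value", "significant", "n_genes", "Associated drugs"],
    ).to_csv(files["pathways"], sep="\t", index=False, float_format="%.6g")
    counts["pathway_tests"] = len(path_rows)
    counts["pathway_significant"] = sum(1 for r in path_rows if r["significant"])

    files["run_log"] = outdir / "run_log.json"
    with open(files["run_log"], "w") as fh:
        json.dump({"version": __version__, "config": asdict(cfg), "counts": counts},
                  fh, indent=2, sort_keys=True)
    return PipelineReport(output_dir=outdir, files=files, counts=counts)
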
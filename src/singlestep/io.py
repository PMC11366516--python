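"""Plain-text writers for pipeline artifacts (TSV/CSV/YAML)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from singlestep.genotypes import MarkerData, QcReport
from singlestep.pedigree import Pedigree, RelationshipMatrix
from singlestep.reml import TraitDataset, VarianceComponents
from singlestep.simdata import SimTruth
from singlestep.ssgblup import MmeSolution
from singlestep.wssgwas import WindowVariance


def write_pedigree_csv(ped: Pedigree, path) -> None:
    rows = []
    for i, a in enumerate(ped.ids):
        s, d = ped.sire[i], ped.dam[i]
        rows.append((a, ped.ids[s] if s >= 0 else "0", ped.ids[d] if d >= 0 else "0"))
    pd.DataFrame(rows, columns=["animal", "sire", "dam"]).to_csv(path, index=False)


def write_plink_text(md: MarkerData, prefix) -> None:
    """Write a .ped/.map pair; dosage k becomes k copies of allele A vs B."""
    mp = pd.DataFrame({
        "chrom": md.chrom, "marker": md.marker_ids,
        "cm": 0, "pos": md.pos,
    })
    mp.to_csv(f"{prefix}.map", sep="\t", header=False, index=False)
    code = {0.0: ("B", "B"), 1.0: ("A", "B"), 2.0: ("A", "A")}
    with open(f"{prefix}.ped", "w") as fh:
        for i, s in enumerate(md.sample_ids):
            alleles = []
            for v in md.calls[i]:
                a, b = code.get(v, ("0", "0")) if not np.isnan(v) else ("0", "0")
                alleles.extend((a, b))
            fh.write(" ".join(["FAM", s, "0", "0", "0", "-9", *alleles]) + "\n")


def write_genotype_tsv(md: MarkerData, geno_path, map_path) -> None:
    df = pd.DataFrame(md.calls, index=list(md.sample_ids),
                      columns=list(md.marker_ids))
    df.to_csv(geno_path, sep="\t", na_rep="NA")
    pd.DataFrame({"marker": md.marker_ids, "chrom": md.chrom, "pos": md.pos}).to_csv(
        map_path, sep="\t", index=False)


def write_phenotypes_csv(data: TraitDataset, path) -> None:
    out = data.records.rename(columns={"animal_id": "animal"})
    out.to_csv(path, index=False)


def write_truth_yaml(truth: SimTruth, path) -> None:
    doc = {
        "realized_h2": float(truth.realized_h2),
        "qtl": truth.qtl.to_dict(orient="records"),
        "true_bv": {str(k): float(v) for k, v in truth.true_bv.items()},
        "fixed_effects": truth.fixed_effects,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_relationship_tsv(rm: RelationshipMatrix, path) -> None:
    """Dense matrices as id-indexed TSV; sparse as coordinate TSV."""
    if sp.issparse(rm.values):
        coo = rm.values.tocoo()
        pd.DataFrame({
            "row_id": [rm.ids[i] for i in coo.row],
            "col_id": [rm.ids[j] for j in coo.col],
            "value": coo.data,
        }).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(rm.values, index=list(rm.ids), columns=list(rm.ids)).to_csv(
            path, sep="\t")


def write_qc_report_yaml(report: QcReport, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(report.to_dict(), fh, sort_keys=False)


def write_vc_yaml(vc: VarianceComponents, path) -> None:
    doc = {
        "sigma_a2": float(vc.sigma_a2),
        "sigma_pe2": float(vc.sigma_pe2),
        "sigma_e2": float(vc.sigma_e2),
        "h2": float(vc.h2),
        "h2_se": None if np.isnan(vc.h2_se) else float(vc.h2_se),
        "se": {k: float(v) for k, v in vc.se.items()},
        "converged": bool(vc.converged),
        "n_iter": int(vc.n_iter),
        "loglik": float(vc.loglik),
        "flags": list(vc.flags),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_solutions_tsv(sol: MmeSolution, path) -> None:
    df = pd.DataFrame({"animal_id": list(sol.ped_ids), "ebv": sol.a_hat})
    if sol.pev is not None:
        df["pev"] = sol.pev
        df["accuracy"] = sol.accuracy
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_scan_tsv(wv: WindowVariance, path) -> None:
    cols = ["chrom", "start_bp", "end_bp", "n_snp", "pct_var"]
    wv.windows[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_regions_tsv(regions: pd.DataFrame, path) -> None:
    """Tables-style report: SSC, position in Mb (2 decimals), variance %,
    SNP count, genes; exact bp retained alongside."""
    out = regions.copy()
    out["position_mb"] = [
        f"{s / 1e6:.2f}-{e / 1e6:.2f}" for s, e in zip(out["start_bp"], out["end_bp"])
    ]
    cols = ["chrom", "position_mb", "max_pct", "n_snp", "start_bp", "end_bp"]
    if "genes" in out.columns:
        cols.insert(4, "genes")
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.4g")
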
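"""File formats: phased VCF panels, call VCFs, sparse count TSVs, manifests.

Panels and call sets travel as bi-allelic VCF (written and read with
pysam); cell-by-locus allele counts as sparse triplet TSV with sidecar
site/cell index files; LD profiles and error models as TSV; run manifests
as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .ld_refine import CellAlleleMatrix, DeNovoCall, LDProfile
from .simulate import ReferencePanel

__all__ = [
    "write_panel_vcf",
    "read_panel_vcf",
    "write_germline_vcf",
    "write_denovo_vcf",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_profile_tsv",
    "read_profile_tsv",
    "write_error_model_tsv",
    "write_manifest",
]


def _vcf_header(chrom: str, length: int, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={chrom},length={length}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in samples:
        header.add_sample(s)
    return header


def write_panel_vcf(panel: ReferencePanel, path: str | Path) -> None:
    """Write a phased panel as bi-allelic VCF, two haplotypes per sample."""
    if panel.n_hap % 2:
        raise ValueError("panel VCF needs an even number of haplotypes")
    samples = [f"panel{i:04d}" for i in range(panel.n_hap // 2)]
    header = _vcf_header(panel.chrom, int(panel.positions[-1]) + 1, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in range(panel.n_sites):
            rec = vcf.new_record(
                contig=panel.chrom,
                start=int(panel.positions[m]) - 1,
                stop=int(panel.positions[m]),
                alleles=(panel.ref[m], panel.alt[m]),
            )
            for i, s in enumerate(samples):
                rec.samples[s]["GT"] = (
                    int(panel.haplotypes[2 * i, m]),
                    int(panel.haplotypes[2 * i + 1, m]),
                )
                rec.samples[s].phased = True
            vcf.write(rec)


def read_panel_vcf(path: str | Path) -> ReferencePanel:
    positions, ref, alt, rows = [], [], [], []
    chrom = "1"
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError("panel must be bi-allelic")
            chrom = rec.chrom
            positions.append(rec.pos)
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            hap_row = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                if len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError("panel genotypes must be diploid and called")
                hap_row.extend(gt)
            rows.append(hap_row)
    haplotypes = np.asarray(rows, dtype=np.int8).T
    return ReferencePanel(
        chrom=chrom, positions=np.asarray(positions), ref=ref, alt=alt,
        haplotypes=haplotypes,
    )


def write_germline_vcf(
    path: str | Path,
    chrom: str,
    records: list[dict],
    sample: str = "sample",
    contig_len: int | None = None,
) -> None:
    """Refined germline calls with GP posteriors and refinement status.

    Each record dict needs pos, ref, alt, genotype, gp (3 floats),
    status, and optionally phased (bool, alt on haplotype 1 first).
    """
    length = contig_len or (max(r["pos"] for r in records) + 1 if records else 2)
    header = _vcf_header(chrom, length, [sample])
    header.add_line(
        '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype posterior">'
    )
    header.add_line(
        '##INFO=<ID=STATUS,Number=1,Type=String,Description="Refinement status">'
    )
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for r in records:
            rec = vcf.new_record(
                contig=chrom, start=r["pos"] - 1, stop=r["pos"],
                alleles=(r["ref"], r["alt"]),
            )
            rec.info["STATUS"] = r.get("status", "germline_kept")
            g = r["genotype"]
            if r.get("phased") is not None and g == 1:
                gt = (1, 0) if r["phased"] else (0, 1)
                rec.samples[sample]["GT"] = gt
                rec.samples[sample].phased = True
            else:
                rec.samples[sample]["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]
            rec.samples[sample]["GP"] = tuple(float(x) for x in r["gp"])
            vcf.write(rec)


def write_denovo_vcf(
    path: str | Path,
    chrom: str,
    calls: list[DeNovoCall],
    alleles: dict[int, tuple[str, str]],
    contig_len: int | None = None,
    filters: dict[int, str] | None = None,
) -> None:
    """De novo SNVs with LD refinement annotations in INFO."""
    length = contig_len or (max(c.position for c in calls) + 1 if calls else 2)
    header = _vcf_header(chrom, length, [])
    for line in (
        '##INFO=<ID=PS_SCORE,Number=1,Type=Float,Description="LD refinement score">',
        '##INFO=<ID=ORIENTATION,Number=1,Type=String,Description="Phase orientation">',
        '##INFO=<ID=N_CELLS_INFORMATIVE,Number=1,Type=Integer,Description="Informative cells">',
        '##INFO=<ID=CLASS,Number=1,Type=String,Description="Somatic classification">',
        '##FILTER=<ID=dp_low,Description="Pooled depth below threshold">',
        '##FILTER=<ID=baf_error_like,Description="BAF below sequencing-error threshold">',
        '##FILTER=<ID=svm_fail,Description="SVM probability below 0.5">',
    ):
        header.add_line(line)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for c in calls:
            ref, alt = alleles[c.site_index]
            rec = vcf.new_record(
                contig=chrom, start=c.position - 1, stop=c.position,
                alleles=(ref, alt),
            )
            rec.info["PS_SCORE"] = float(c.ps)
            rec.info["ORIENTATION"] = c.orientation
            rec.info["N_CELLS_INFORMATIVE"] = c.n_informative_cells
            rec.info["CLASS"] = c.classification.value
            if filters and c.site_index in filters:
                rec.filter.add(filters[c.site_index])
            else:
                rec.filter.add("PASS")
            vcf.write(rec)


def write_matrix_tsv(matrix: CellAlleleMatrix, prefix: str | Path) -> None:
    """Sparse triplet TSV plus site and cell index sidecars."""
    prefix = Path(prefix)
    sites = pd.DataFrame(
        {
            "site_index": np.arange(matrix.n_sites),
            "chrom": matrix.chrom,
            "pos": matrix.positions,
            "allele1": matrix.allele1 or ["N"] * matrix.n_sites,
            "allele2": matrix.allele2 or ["N"] * matrix.n_sites,
            "phased": matrix.phased.astype(int),
        }
    )
    sites.to_csv(prefix.with_suffix(".sites.tsv"), sep="\t", index=False)
    cells = matrix.cell_ids or [f"cell{j:05d}" for j in range(matrix.n_cells)]
    pd.DataFrame({"cell_id": cells}).to_csv(
        prefix.with_suffix(".cells.tsv"), sep="\t", index=False
    )
    rows, cols = np.nonzero((matrix.c1 + matrix.c2) > 0)
    trip = pd.DataFrame(
        {
            "cell_id": [cells[j] for j in cols],
            "site_index": rows,
            "count_allele1": matrix.c1[rows, cols],
            "count_allele2": matrix.c2[rows, cols],
        }
    )
    trip.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t", index=False)


def read_matrix_tsv(prefix: str | Path) -> CellAlleleMatrix:
    prefix = Path(prefix)
    sites = pd.read_csv(prefix.with_suffix(".sites.tsv"), sep="\t")
    cells = pd.read_csv(prefix.with_suffix(".cells.tsv"), sep="\t")["cell_id"].tolist()
    trip = pd.read_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
    cell_index = {c: j for j, c in enumerate(cells)}
    c1 = np.zeros((len(sites), len(cells)), dtype=np.int32)
    c2 = np.zeros_like(c1)
    for _, row in trip.iterrows():
        j = cell_index[row["cell_id"]]
        c1[row["site_index"], j] = row["count_allele1"]
        c2[row["site_index"], j] = row["count_allele2"]
    return CellAlleleMatrix(
        positions=sites["pos"].to_numpy(),
        c1=c1,
        c2=c2,
        phased=sites["phased"].to_numpy().astype(bool),
        chrom=str(sites["chrom"].iloc[0]),
        allele1=sites["allele1"].tolist(),
        allele2=sites["allele2"].tolist(),
        cell_ids=cells,
    )


def write_profile_tsv(profile: LDProfile, path: str | Path) -> None:
    edges = profile.bin_edges
    pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "score2": profile.score2,
            "n2": profile.n2,
            "score3": profile.score3,
            "n3": profile.n3,
        }
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> LDProfile:
    df = pd.read_csv(path, sep="\t")
    edges = np.concatenate([df["bin_lo"].to_numpy(float), [float(df["bin_hi"].iloc[-1])]])
    return LDProfile(
        bin_edges=edges,
        score2=df["score2"].to_numpy(float),
        n2=df["n2"].to_numpy(np.int64),
        score3=df["score3"].to_numpy(float),
        n3=df["n3"].to_numpy(np.int64),
    )


def write_error_model_tsv(model, path: str | Path) -> None:
    pd.DataFrame(model.to_table(), columns=["category", "threshold", "n"]).to_csv(
        path, sep="\t", index=False
    )


def write_manifest(path: str | Path, **entries) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    Path(path).write_text(json.dumps(entries, indent=2, default=_default, sort_keys=True))
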
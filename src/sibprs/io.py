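"""Standard-format I/O: PLINK BED/BIM/FAM, VCF, phenotype/pedigree tables,
predictor JSON, and commented CSV tables.

Allele convention: the counted allele (dosage = number of copies) is
allele-1 of the BIM and ALT of the VCF; this is recorded in every
predictor file so external scoring tools agree.  Missing genotypes are
mean-imputed per variant at load time.
"""
from __future__ import annotations

import hashlib
import io as _stdio
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Pedigree, PhenotypeTable
from .train import Predictor, PredictorEnsemble

__all__ = [
    "write_plink",
    "read_plink",
    "write_vcf",
    "read_vcf",
    "write_pedigree_fam",
    "read_pedigree_fam",
    "write_phenotypes",
    "read_phenotypes",
    "write_ensemble",
    "read_ensemble",
    "write_table",
    "read_table",
    "config_hash",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major


def write_plink(G: GenotypeMatrix, pedigree: Pedigree, prefix) -> None:
    """Write a BED/BIM/FAM triplet (hard-call dosages, SNP-major BED).

    Two-bit codes per sample: 00 = 2 copies of allele1, 10 = 1 copy,
    11 = 0 copies, 01 = missing (never produced here).
    """
    prefix = Path(prefix)
    ped = pedigree.table.set_index("individual_id").loc[list(G.sample_ids)]
    fam = pd.DataFrame(
        {
            "family_id": ped["family_id"].to_numpy(),
            "individual_id": ped.index,
            "father_id": ped["father_id"].to_numpy(),
            "mother_id": ped["mother_id"].to_numpy(),
            "sex": ped["sex"].to_numpy(),
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": 1,
            "variant_id": G.variant_ids,
            "cm": 0,
            "pos": np.arange(1, G.n_variants + 1),
            "allele1": G.variant_meta["allele1"].to_numpy(),
            "allele2": G.variant_meta["allele2"].to_numpy(),
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n = G.n_samples
    dose = np.rint(G.dosages).astype(np.uint8)
    code = np.empty_like(dose)
    code[dose == 2] = 0b00
    code[dose == 1] = 0b10
    code[dose == 0] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.zeros((n_bytes * 4, G.n_variants), dtype=np.uint8)
    padded[:n] = code
    packed = (
        padded[0::4]
        | (padded[1::4] << 2)
        | (padded[2::4] << 4)
        | (padded[3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.T.tobytes())  # variant-major blocks


def read_plink(prefix):
    """Load a BED/BIM/FAM triplet into (GenotypeMatrix, Pedigree).

    Missing calls (code 01) are mean-imputed per variant.  The FAM has no
    generation column; individuals with both parent ids "0" are founders.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "variant_id", "cm", "pos", "allele1", "allele2"],
        dtype=str,
    )
    n, p = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK BED file")
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != n_bytes * p:
        raise ValueError(
            f"{prefix}.bed: size mismatch (expected {n_bytes * p} body bytes, got {len(body)})"
        )
    blocks = body.reshape(p, n_bytes)
    codes = np.empty((p, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = blocks & 0b11
    codes[:, 1::4] = (blocks >> 2) & 0b11
    codes[:, 2::4] = (blocks >> 4) & 0b11
    codes[:, 3::4] = (blocks >> 6) & 0b11
    codes = codes[:, :n].T  # (n, p)
    dose = np.empty((n, p), dtype=np.float32)
    dose[codes == 0b00] = 2
    dose[codes == 0b10] = 1
    dose[codes == 0b11] = 0
    missing = codes == 0b01
    dose[missing] = np.nan
    dose = _mean_impute(dose)
    ped = pd.DataFrame(
        {
            "individual_id": fam["individual_id"],
            "family_id": fam["family_id"],
            "father_id": fam["father_id"],
            "mother_id": fam["mother_id"],
            "sex": fam["sex"].astype(int, errors="ignore"),
            "generation": np.where(
                (fam["father_id"] == "0") & (fam["mother_id"] == "0"), "founder", "offspring"
            ),
        }
    )
    meta = pd.DataFrame(
        {
            "freq": np.nanmean(dose, axis=0) / 2.0,
            "allele1": bim["allele1"].to_numpy(),
            "allele2": bim["allele2"].to_numpy(),
        },
        index=bim["variant_id"].to_numpy(),
    )
    gm = GenotypeMatrix(
        fam["individual_id"].to_numpy(dtype=object),
        bim["variant_id"].to_numpy(dtype=object),
        dose,
        meta,
    )
    return gm, Pedigree(ped)


def _mean_impute(dose: np.ndarray) -> np.ndarray:
    """Replace NaN entries with the per-variant mean dosage."""
    nan_cols = np.isnan(dose).any(axis=0)
    if nan_cols.any():
        col_mean = np.nanmean(dose[:, nan_cols], axis=0)
        col_mean = np.nan_to_num(col_mean, nan=0.0)
        for j, c in enumerate(np.flatnonzero(nan_cols)):
            col = dose[:, c]
            col[np.isnan(col)] = col_mean[j]
    return dose


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write hard-call genotypes as an uncompressed VCF 4.2 (GT field).

    Allele1 (the counted allele) is ALT; dosage 0/1/2 becomes 0/0, 0/1,
    1/1.  Fractional dosages are rounded.
    """
    path = Path(path)
    dose = np.rint(G.dosages).astype(np.uint8)
    gt = np.array(["0/0", "0/1", "1/1"], dtype=object)[dose]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in G.sample_ids) + "\n")
        ref = G.variant_meta["allele2"].to_numpy()
        alt = G.variant_meta["allele1"].to_numpy()
        for j in range(G.n_variants):
            fields = [
                "1", str(j + 1), str(G.variant_ids[j]), str(ref[j]), str(alt[j]),
                ".", "PASS", ".", "GT",
            ]
            fh.write("\t".join(fields) + "\t" + "\t".join(gt[:, j]) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Load GT dosages from a VCF via cyvcf2; missing calls mean-imputed.

    The counted allele is ALT, so dosage = number of ALT alleles.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    ids, refs, alts, cols = [], [], [], []
    for rec in vcf:
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        g = np.array(rec.genotypes, dtype=float)[:, :2]
        d = g.sum(axis=1)
        d[(g < 0).any(axis=1)] = np.nan  # any missing allele -> missing call
        cols.append(d)
    vcf.close()
    dose = _mean_impute(np.column_stack(cols).astype(np.float32))
    meta = pd.DataFrame(
        {"freq": np.nanmean(dose, axis=0) / 2.0, "allele1": alts, "allele2": refs},
        index=np.array(ids, dtype=object),
    )
    return GenotypeMatrix(samples, np.array(ids, dtype=object), dose, meta)


def write_pedigree_fam(pedigree: Pedigree, path) -> None:
    """FAM-style pedigree (family, individual, father, mother, sex, -9)."""
    t = pedigree.table
    out = pd.DataFrame(
        {
            "family_id": t["family_id"],
            "individual_id": t["individual_id"],
            "father_id": t["father_id"],
            "mother_id": t["mother_id"],
            "sex": t["sex"],
            "phenotype": -9,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_pedigree_fam(path) -> Pedigree:
    fam = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
        dtype=str,
    )
    return Pedigree(
        pd.DataFrame(
            {
                "individual_id": fam["individual_id"],
                "family_id": fam["family_id"],
                "father_id": fam["father_id"],
                "mother_id": fam["mother_id"],
                "sex": fam["sex"],
                "generation": np.where(
                    (fam["father_id"] == "0") & (fam["mother_id"] == "0"),
                    "founder",
                    "offspring",
                ),
            }
        )
    )


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    """Tab-delimited phenotype table with header."""
    phen.frame().to_csv(path, sep="\t", index=False)


def read_phenotypes(path, trait: str | None = None, kind: str = "binary") -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t")
    if trait is not None:
        df = df[df["trait"] == trait]
    elif df["trait"].nunique() == 1:
        trait = df["trait"].iloc[0]
    else:
        raise ValueError("phenotype file holds multiple traits; specify one")
    values = pd.Series(df["value"].to_numpy(), index=df["individual_id"].to_numpy())
    return PhenotypeTable(values, trait, kind)


def write_ensemble(ensemble: PredictorEnsemble, path) -> None:
    """Serialize an ensemble as JSON (nonzero weights only)."""
    payload = {
        "trait": ensemble.trait,
        "trait_kind": ensemble.trait_kind,
        "counted_allele": "allele1/ALT",
        "predictors": [],
    }
    for p in ensemble.predictors:
        nz = p.weights != 0
        payload["predictors"].append(
            {
                "variant_ids": [str(v) for v in p.variant_ids[nz]],
                "weights": [float(w) for w in p.weights[nz]],
                "chosen_lambda": p.chosen_lambda,
                "metric_name": p.metric_name,
                "metric_value": p.metric_value,
                "n_holdout": int(len(p.holdout_ids)),
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ensemble(path) -> PredictorEnsemble:
    payload = json.loads(Path(path).read_text())
    preds = [
        Predictor(
            variant_ids=np.array(d["variant_ids"], dtype=object),
            weights=np.array(d["weights"], dtype=float),
            chosen_lambda=d["chosen_lambda"],
            metric_name=d["metric_name"],
            metric_value=d["metric_value"],
            trait=payload["trait"],
        )
        for d in payload["predictors"]
    ]
    return PredictorEnsemble(preds, payload["trait"], payload["trait_kind"])


def config_hash(obj) -> str:
    """Short stable hash of a configuration object for output headers."""
    try:
        from dataclasses import asdict, is_dataclass

        if is_dataclass(obj):
            obj = asdict(obj)
    except TypeError:
        pass
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: int, cfg_hash: str) -> None:
    """CSV with a provenance comment header (# seed=.. config=..)."""
    buf = _stdio.StringIO()
    df.to_csv(buf, index=False)
    Path(path).write_text(f"# seed={seed} config={cfg_hash}\n" + buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
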
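"""Minimal VCF 4.2 I/O for GT-only cohort callsets.

Reading is delegated to :mod:`cyvcf2`; writing emits plain-text VCF so that
cohorts remain diffable and byte-reproducible. Only the GT FORMAT field is
supported -- that is all the downstream analyses consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import ParseError

#: Sentinel for a missing genotype in dosage matrices.
MISSING = -1


@dataclass
class VcfRecord:
    """One VCF data line; genotype entries are allele-index pairs.

    ``genotypes[i]`` is a pair of allele indices for sample ``i``; ``None``
    in place of an index encodes a missing allele (``.``).
    """

    chrom: str
    pos: int  # 1-based, as in VCF
    vid: str
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[Optional[int], Optional[int]]] = field(default_factory=list)

    @property
    def n_alts(self) -> int:
        return len(self.alts)

    def alt_dosages(self, alt_index: int = 0) -> np.ndarray:
        """Per-sample count of alternate allele ``alt_index`` (0-based).

        A genotype with any missing allele yields :data:`MISSING`.
        """
        allele = alt_index + 1
        out = np.empty(len(self.genotypes), dtype=np.int8)
        for i, (a1, a2) in enumerate(self.genotypes):
            if a1 is None or a2 is None:
                out[i] = MISSING
            else:
                out[i] = (a1 == allele) + (a2 == allele)
        return out


def _gt_string(pair: tuple[Optional[int], Optional[int]]) -> str:
    a1, a2 = pair
    return f"{'.' if a1 is None else a1}/{'.' if a2 is None else a2}"


def write_vcf(path: str | Path, samples: Sequence[str], records: Sequence[VcfRecord]) -> None:
    """Write a GT-only VCF 4.2 file (uncompressed text)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for rec in records:
            if rec.chrom not in contigs:
                contigs.append(rec.chrom)
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for rec in records:
            if len(rec.genotypes) != len(samples):
                raise ParseError(
                    f"record {rec.vid}: {len(rec.genotypes)} genotypes for {len(samples)} samples"
                )
            fields = [
                rec.chrom,
                str(rec.pos),
                rec.vid,
                rec.ref,
                ",".join(rec.alts),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields.extend(_gt_string(g) for g in rec.genotypes)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> tuple[list[str], list[VcfRecord]]:
    """Read a VCF into :class:`VcfRecord` objects via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records: list[VcfRecord] = []
    for v in vcf:
        gts = []
        for g in v.genotypes:
            a1 = None if g[0] < 0 else int(g[0])
            a2 = None if g[1] < 0 else int(g[1])
            gts.append((a1, a2))
        records.append(
            VcfRecord(
                chrom=v.CHROM,
                pos=int(v.POS),
                vid=v.ID if v.ID is not None else f"{v.CHROM}:{v.POS}",
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=gts,
            )
        )
    vcf.close()
    return samples, records


def dosage_matrix(records: Sequence[VcfRecord]) -> np.ndarray:
    """Stack bi-allelic records into a samples x variants dosage matrix."""
    cols = []
    for rec in records:
        if rec.n_alts != 1:
            raise ParseError(f"record {rec.vid} is multi-allelic; decompose it first")
        cols.append(rec.alt_dosages(0))
    if not cols:
        return np.zeros((0, 0), dtype=np.int8)
    return np.stack(cols, axis=1)
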
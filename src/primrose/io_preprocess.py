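"""Reading standard formats and the site/genotype-level filtering cascade.

This module is the entry point of the pipeline: it turns a VCF into a
:class:`GenotypeMatrix`, applies GATK-style hard filters at the site level,
allelic-depth / allele-balance filters at the genotype level, and annotates
reference positions by coding degeneracy (0-fold / 4-fold) and by a neutral
accessibility mask (intergenic sites at least 2 kb from genes, outside
repeats).

Coordinate conventions: VCF is 1-based, BED/GFF readers deliver 0-based
half-open intervals; everything stored internally is 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

MISSING = -1

#: site-class codes used by SiteClassAnnotation
INTERGENIC_FAR = 0
INTERGENIC_NEAR = 1
OTHER_CODING = 2
ZEROFOLD = 3
FOURFOLD = 4
MASKED_REPEAT = 5

CLASS_NAMES = {
    INTERGENIC_FAR: "intergenic-far",
    INTERGENIC_NEAR: "intergenic-near",
    OTHER_CODING: "other-coding",
    ZEROFOLD: "0-fold",
    FOURFOLD: "4-fold",
    MASKED_REPEAT: "masked-repeat",
}

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class VcfParseError(ValueError):
    """Raised when a VCF data line cannot be interpreted."""


class UnsupportedPloidyError(ValueError):
    """Raised when a genotype call is not diploid."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One VCF data line with the annotations the filter cascade consumes.

    Annotation fields are ``None`` when absent from the VCF INFO column;
    absence is distinct from zero and makes the corresponding filter
    criterion pass.
    """

    chrom: str
    pos: int                       # 1-based, as in the VCF
    ref: str
    alt: str
    is_biallelic: bool = True
    qd: float | None = None
    mq: float | None = None
    fs: float | None = None
    mq_rank_sum: float | None = None
    read_pos_rank_sum: float | None = None
    dp: float | None = None
    inbreeding_coeff: float | None = None
    ad: np.ndarray | None = None   # (n_samples, 2) ref/alt depths, -1 absent
    line_no: int | None = None


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix: individuals x biallelic sites.

    ``calls`` holds the count of alternate (or derived, once polarized)
    alleles per individual and site: 0, 1, 2, or ``MISSING`` (-1).
    Positions are stored 0-based and strictly increasing per chromosome.
    """

    samples: list[str]
    chrom: np.ndarray              # (n_sites,) str
    pos: np.ndarray                # (n_sites,) int64, 0-based
    ref: np.ndarray                # (n_sites,) str
    alt: np.ndarray                # (n_sites,) str
    calls: np.ndarray              # (n_samples, n_sites) int8
    populations: list[str] | None = None
    morphs: list[str] | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.calls.shape != (len(self.samples), len(self.pos)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.pos)} sites"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            calls=self.calls[:, index],
            populations=self.populations,
            morphs=self.morphs,
        )

    def take_samples(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            calls=self.calls[index, :],
            populations=[self.populations[i] for i in index] if self.populations else None,
            morphs=[self.morphs[i] for i in index] if self.morphs else None,
        )

    def alt_counts(self) -> np.ndarray:
        """Sum of alternate-allele dosages over called genotypes, per site."""
        c = self.calls.astype(np.int64)
        return np.where(c >= 0, c, 0).sum(axis=0)

    def called_haplotypes(self) -> np.ndarray:
        """Number of called haplotypes (2 x called genotypes) per site."""
        return 2 * (self.calls >= 0).sum(axis=0)

    def missingness(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def is_polymorphic(self) -> np.ndarray:
        ac = self.alt_counts()
        an = self.called_haplotypes()
        return (ac > 0) & (ac < an)

    def subset_population(self, population: str) -> "GenotypeMatrix":
        if self.populations is None:
            raise ValueError("matrix has no population labels")
        idx = [i for i, p in enumerate(self.populations) if p == population]
        return self.take_samples(idx)


@dataclass
class SiteClassAnnotation:
    """Per-chromosome int8 arrays assigning each position one site class."""

    classes: dict[str, np.ndarray]

    def sites_of_class(self, chrom: str, code: int) -> np.ndarray:
        return np.flatnonzero(self.classes[chrom] == code)

    def class_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        return self.classes[chrom][pos]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {name: 0 for name in CLASS_NAMES.values()}
        for arr in self.classes.values():
            for code, name in CLASS_NAMES.items():
                out[name] += int((arr == code).sum())
        return out


@dataclass
class AccessibilityMask:
    """Boolean per-chromosome arrays; True marks callable/usable sites."""

    mask: dict[str, np.ndarray]

    def n_accessible(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self.mask[chrom].sum())
        return int(sum(m.sum() for m in self.mask.values()))

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.mask[chrom]


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path: str, populations: Mapping[str, str] | None = None,
             morphs: Mapping[str, str] | None = None
             ) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Read a VCF 4.x file into a genotype matrix plus per-site records.

    Multiallelic lines are kept in the record list (flagged
    ``is_biallelic=False``) with all-missing dosages so that downstream
    filters can account for and drop them.

    Parameters
    ----------
    path:
        VCF path (plain or bgzipped).
    populations, morphs:
        Optional sample -> label maps attached to the matrix.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    dosages: list[np.ndarray] = []
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []

    def _info(v, key):
        val = v.INFO.get(key)
        return float(val) if val is not None else None

    for line_no, v in enumerate(vcf, start=1):
        try:
            if len(v.gt_types) != len(samples):
                raise VcfParseError(f"VCF line {line_no}: truncated genotype field")
            ploidy = v.ploidy
            if ploidy != 2:
                raise UnsupportedPloidyError(
                    f"VCF line {line_no}: ploidy {ploidy}, only diploid supported"
                )
            biallelic = len(v.ALT) == 1
            # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
            gt = v.gt_types.astype(np.int8)
            gt[gt == 3] = MISSING
            if not biallelic:
                gt[:] = MISSING
            ad = None
            try:
                ad_raw = v.format("AD")
            except Exception:
                ad_raw = None
            if ad_raw is not None and ad_raw.shape[1] >= 2:
                ad = ad_raw[:, :2].astype(np.int32)
            rec = VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=",".join(v.ALT) if v.ALT else ".",
                is_biallelic=biallelic,
                qd=_info(v, "QD"),
                mq=_info(v, "MQ"),
                fs=_info(v, "FS"),
                mq_rank_sum=_info(v, "MQRankSum"),
                read_pos_rank_sum=_info(v, "ReadPosRankSum"),
                dp=_info(v, "DP"),
                inbreeding_coeff=_info(v, "InbreedingCoeff"),
                ad=ad,
                line_no=line_no,
            )
        except (UnsupportedPloidyError, VcfParseError):
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise VcfParseError(f"VCF line {line_no}: {exc}") from exc
        records.append(rec)
        dosages.append(gt)
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        refs.append(v.REF)
        alts.append(rec.alt)

    calls = (np.vstack(dosages).T if dosages
             else np.zeros((len(samples), 0), dtype=np.int8))
    matrix = GenotypeMatrix(
        samples=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=calls,
        populations=[populations[s] for s in samples] if populations else None,
        morphs=[morphs[s] for s in samples] if morphs else None,
    )
    return matrix, records


def write_vcf(matrix: GenotypeMatrix, path: str,
              records: Sequence[VariantRecord] | None = None,
              contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and AD where records supply it)."""
    rec_by_key = {}
    if records is not None:
        rec_by_key = {(r.chrom, r.pos): r for r in records}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for c, L in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={L}>\n")
        else:
            for c in dict.fromkeys(matrix.chrom.tolist()):
                fh.write(f"##contig=<ID={c}>\n")
        for key, desc, typ in [
            ("QD", "Quality by depth", "Float"), ("MQ", "Mapping quality", "Float"),
            ("FS", "Phred strand bias", "Float"),
            ("MQRankSum", "MQ rank sum", "Float"),
            ("ReadPosRankSum", "Read position rank sum", "Float"),
            ("DP", "Site depth", "Float"),
            ("InbreedingCoeff", "Site inbreeding coefficient", "Float"),
        ]:
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(matrix.n_sites):
            rec = rec_by_key.get((matrix.chrom[j], int(matrix.pos[j]) + 1))
            info_parts = []
            if rec is not None:
                for key, attr in [("QD", "qd"), ("MQ", "mq"), ("FS", "fs"),
                                  ("MQRankSum", "mq_rank_sum"),
                                  ("ReadPosRankSum", "read_pos_rank_sum"),
                                  ("DP", "dp"),
                                  ("InbreedingCoeff", "inbreeding_coeff")]:
                    val = getattr(rec, attr)
                    if val is not None:
                        info_parts.append(f"{key}={val:.4g}")
            info = ";".join(info_parts) if info_parts else "."
            has_ad = rec is not None and rec.ad is not None
            fmt = "GT:AD" if has_ad else "GT"
            cols = []
            for i in range(matrix.n_samples):
                g = gt_strings[int(matrix.calls[i, j])]
                if has_ad:
                    a = rec.ad[i]
                    g += f":{int(a[0])},{int(a[1])}" if a[0] >= 0 else ":.,."
                cols.append(g)
            fh.write(f"{matrix.chrom[j]}\t{int(matrix.pos[j]) + 1}\t.\t"
                     f"{matrix.ref[j]}\t{matrix.alt[j]}\t.\t.\t{info}\t{fmt}\t"
                     + "\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# filtering cascade
# ---------------------------------------------------------------------------

@dataclass
class SiteFilterThresholds:
    """GATK-style hard-filter thresholds; a record passes a criterion when
    the annotation is missing."""

    min_qd: float = 2.0
    min_mq: float = 40.0
    max_fs: float = 60.0
    min_mq_rank_sum: float = -12.5
    min_read_pos_rank_sum: float = -8.0
    dp_low_factor: float = 0.5     # fail when DP < 0.5 x mean
    dp_high_factor: float = 3.0    # fail when DP > 3 x mean
    min_inbreeding_coeff: float = -0.99


def site_filter_flags(rec: VariantRecord, depth_mean: float,
                      thresholds: SiteFilterThresholds) -> dict[str, bool]:
    """Evaluate each hard-filter criterion; True means the criterion passes."""
    t = thresholds
    return {
        "QD": rec.qd is None or rec.qd > t.min_qd,
        "MQ": rec.mq is None or rec.mq > t.min_mq,
        "FS": rec.fs is None or rec.fs < t.max_fs,
        "MQRankSum": rec.mq_rank_sum is None or rec.mq_rank_sum > t.min_mq_rank_sum,
        "ReadPosRankSum": (rec.read_pos_rank_sum is None
                           or rec.read_pos_rank_sum > t.min_read_pos_rank_sum),
        "DP": rec.dp is None or (t.dp_low_factor * depth_mean <= rec.dp
                                 <= t.dp_high_factor * depth_mean),
        "InbreedingCoeff": (rec.inbreeding_coeff is None
                            or rec.inbreeding_coeff >= t.min_inbreeding_coeff),
    }


def apply_site_filters(records: Sequence[VariantRecord], depth_mean: float,
                       thresholds: SiteFilterThresholds | None = None
                       ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Apply site-level hard filters; returns surviving records plus a
    per-criterion failure report.

    ``depth_mean`` is the dataset mean of site DP, the reference for the
    half-to-three-fold depth band.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    thresholds = thresholds or SiteFilterThresholds()
    kept: list[VariantRecord] = []
    fails: dict[str, int] = {}
    for rec in records:
        flags = site_filter_flags(rec, depth_mean, thresholds)
        if all(flags.values()):
            kept.append(rec)
        else:
            for k, ok in flags.items():
                if not ok:
                    fails[k] = fails.get(k, 0) + 1
    report = pd.DataFrame(
        {"criterion": list(fails), "n_failed": list(fails.values())}
    )
    logger.info("site filters: %d/%d records retained", len(kept), len(records))
    return kept, report


def apply_genotype_filters(matrix: GenotypeMatrix,
                           records: Sequence[VariantRecord],
                           min_ad: int = 6, max_ad: int = 60,
                           ab_low: float = 0.30, ab_high: float = 0.70
                           ) -> tuple[GenotypeMatrix, list[VariantRecord]]:
    """Allelic-depth and allele-balance filtering.

    Genotypes with total allelic depth < ``min_ad`` or > ``max_ad`` are set
    to missing. Any site carrying a heterozygous call whose allele balance
    AD_alt/(AD_ref+AD_alt) falls outside [``ab_low``, ``ab_high``] is
    removed entirely, since such sites likely harbour systematically
    erroneous heterozygous calls.
    """
    key_to_col = {(c, int(p) + 1): j
                  for j, (c, p) in enumerate(zip(matrix.chrom, matrix.pos))}
    calls = matrix.calls.copy()
    drop_site = np.zeros(matrix.n_sites, dtype=bool)
    n_warned = 0
    for rec in records:
        j = key_to_col.get((rec.chrom, rec.pos))
        if j is None:
            continue
        if rec.ad is None:
            if (calls[:, j] >= 0).any():
                n_warned += 1
            continue
        total = rec.ad.sum(axis=1)
        called = calls[:, j] >= 0
        bad_depth = called & ((total < min_ad) | (total > max_ad))
        calls[bad_depth, j] = MISSING
        het = (calls[:, j] == 1)
        if het.any():
            with np.errstate(invalid="ignore", divide="ignore"):
                ab = np.where(total > 0, rec.ad[:, 1] / np.maximum(total, 1), np.nan)
            ab_het = ab[het]
            if np.any((ab_het < ab_low) | (ab_het > ab_high)):
                drop_site[j] = True
    if n_warned:
        warnings.warn(f"{n_warned} sites had called genotypes but no AD field; "
                      "genotypes retained")
    keep = ~drop_site
    kept_keys = {(c, int(p) + 1)
                 for c, p in zip(matrix.chrom[keep], matrix.pos[keep])}
    out_records = [r for r in records if (r.chrom, r.pos) in kept_keys]
    out = replace(matrix, calls=calls).take_sites(np.flatnonzero(keep))
    return out, out_records


def finalize_callset(matrix: GenotypeMatrix,
                     chromosomes: Iterable[str],
                     records: Sequence[VariantRecord] | None = None,
                     max_missing: float = 0.20) -> GenotypeMatrix:
    """Retain biallelic SNPs on whitelisted chromosomes with per-site
    missingness strictly below ``max_missing``."""
    whitelist = set(chromosomes)
    on_chrom = np.array([c in whitelist for c in matrix.chrom])
    biallelic = np.ones(matrix.n_sites, dtype=bool)
    if records is not None:
        key_bi = {(r.chrom, r.pos): r.is_biallelic for r in records}
        biallelic = np.array([key_bi.get((c, int(p) + 1), True)
                              for c, p in zip(matrix.chrom, matrix.pos)])
    snp = np.array([len(r) == 1 and len(a) == 1 and "," not in a
                    for r, a in zip(matrix.ref, matrix.alt)])
    ok = on_chrom & biallelic & snp & (matrix.missingness() < max_missing)
    if not ok.any():
        warnings.warn("finalize_callset produced an empty callset")
    return matrix.take_sites(np.flatnonzero(ok))


def sample_polymorphic_sites(matrix: GenotypeMatrix, n: int,
                             seed: int) -> GenotypeMatrix:
    """Uniform random subsample (without replacement) of polymorphic sites."""
    poly = np.flatnonzero(matrix.is_polymorphic())
    if n >= len(poly):
        if n > len(poly):
            warnings.warn(
                f"requested {n} polymorphic sites but only {len(poly)} exist; "
                "taking all")
        chosen = poly
    else:
        rng = np.random.default_rng(seed)
        chosen = np.sort(rng.choice(poly, size=n, replace=False))
    return matrix.take_sites(chosen)


# ---------------------------------------------------------------------------
# degeneracy annotation and the neutral accessibility mask
# ---------------------------------------------------------------------------

def _read_gff_df(gff: str | pd.DataFrame) -> pd.DataFrame:
    if isinstance(gff, pd.DataFrame):
        return gff
    import pyranges
    return pyranges.read_gff3(gff).df


def _codon_degeneracy(codon: str) -> np.ndarray:
    """Per-position degeneracy class of one codon (array of 3 codes)."""
    out = np.full(3, OTHER_CODING, dtype=np.int8)
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return out
    aa = CODON_TABLE[codon]
    if aa == "*":
        return out
    for k in range(3):
        n_syn = 0
        for b in "ACGT":
            if b == codon[k]:
                continue
            alt = codon[:k] + b + codon[k + 1:]
            if CODON_TABLE[alt] == aa:
                n_syn += 1
        if n_syn == 3:
            out[k] = FOURFOLD
        elif n_syn == 0:
            out[k] = ZEROFOLD
    return out


def annotate_degeneracy(gff: str | pd.DataFrame, fasta: str,
                        ) -> SiteClassAnnotation:
    """Classify every position by coding degeneracy.

    CDS segments are grouped per transcript (GFF3 ``Parent``), concatenated
    in transcription order with the first segment's phase applied, and each
    codon position is classified: 4-fold when every substitution at it is
    synonymous, 0-fold when none is. Stop codons, ambiguous bases, and
    positions where overlapping transcripts disagree are ``other-coding``.
    Positions inside gene spans but not classified 0-/4-fold are
    ``other-coding``; everything outside genes starts as ``intergenic-far``
    (refined later by :func:`classify_sites`).
    """
    df = _read_gff_df(gff)
    seqs = Fasta(fasta)
    classes = {name: np.full(len(seqs[name]), INTERGENIC_FAR, dtype=np.int8)
               for name in seqs.keys()}

    genes = df[df.Feature.isin(["gene", "mRNA"])]
    for _, g in genes.iterrows():
        if g.Chromosome in classes:
            classes[g.Chromosome][int(g.Start):int(g.End)] = OTHER_CODING

    cds = df[df.Feature == "CDS"].copy()
    if cds.empty:
        return SiteClassAnnotation(classes)
    parent_col = "Parent" if "Parent" in cds.columns else "ID"
    # first committed class wins; conflicts collapse to other-coding
    assigned: dict[str, np.ndarray] = {
        name: np.zeros(len(arr), dtype=bool) for name, arr in classes.items()
    }
    for parent, group in cds.groupby(parent_col, sort=False):
        group = group.sort_values("Start")
        strand = group.Strand.iloc[0]
        chrom = group.Chromosome.iloc[0]
        if chrom not in classes:
            continue
        segs = [(int(s), int(e)) for s, e in zip(group.Start, group.End)]
        positions = np.concatenate([np.arange(s, e) for s, e in segs])
        seq = "".join(str(seqs[chrom][s:e]) for s, e in segs).upper()
        if strand == "-":
            positions = positions[::-1]
            seq = seq.translate(_COMPLEMENT)[::-1]
            phase_raw = group.Frame.iloc[-1]
        else:
            phase_raw = group.Frame.iloc[0]
        try:
            phase = int(phase_raw)
        except (TypeError, ValueError):
            phase = 0
        seq = seq[phase:]
        positions = positions[phase:]
        if len(seq) % 3 != 0:
            warnings.warn(f"CDS of {parent} has length {len(seq)} after phase "
                          "adjustment; trailing bases left as other-coding")
        arr = classes[chrom]
        done = assigned[chrom]
        for c0 in range(0, len(seq) - len(seq) % 3, 3):
            deg = _codon_degeneracy(seq[c0:c0 + 3])
            for k in range(3):
                p = positions[c0 + k]
                if done[p] and arr[p] != deg[k]:
                    arr[p] = OTHER_CODING
                else:
                    arr[p] = deg[k]
                    done[p] = True
    return SiteClassAnnotation(classes)


def classify_sites(annotation: SiteClassAnnotation,
                   gff: str | pd.DataFrame,
                   repeat_bed: str | pd.DataFrame | None = None,
                   flank: int = 2000) -> SiteClassAnnotation:
    """Refine a degeneracy annotation with near-gene and repeat classes.

    Intergenic positions within ``flank`` bp of a gene become
    ``intergenic-near``; repeat/centromere intervals override everything as
    ``masked-repeat``.
    """
    df = _read_gff_df(gff)
    classes = {c: a.copy() for c, a in annotation.classes.items()}
    genes = df[df.Feature == "gene"]
    if genes.empty:
        genes = df[df.Feature == "mRNA"]
    for _, g in genes.iterrows():
        if g.Chromosome not in classes:
            continue
        arr = classes[g.Chromosome]
        for s, e in ((max(0, int(g.Start) - flank), int(g.Start)),
                     (int(g.End), min(len(arr), int(g.End) + flank))):
            seg = arr[s:e]
            seg[seg == INTERGENIC_FAR] = INTERGENIC_NEAR
    if repeat_bed is not None:
        rep = _read_bed_df(repeat_bed)
        for _, r in rep.iterrows():
            if r.Chromosome in classes:
                arr = classes[r.Chromosome]
                arr[int(r.Start):min(len(arr), int(r.End))] = MASKED_REPEAT
    return SiteClassAnnotation(classes)


def _read_bed_df(bed: str | pd.DataFrame) -> pd.DataFrame:
    if isinstance(bed, pd.DataFrame):
        return bed
    df = pd.read_csv(bed, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["Chromosome", "Start", "End"])
    return df


def build_neutral_mask(gff: str | pd.DataFrame | None,
                       repeat_bed: str | pd.DataFrame | None,
                       chrom_lengths: Mapping[str, int],
                       flank: int = 2000) -> AccessibilityMask:
    """Accessibility mask for putatively neutral intergenic sites.

    Masks out gene bodies (introns and exons), ``flank`` bp up/downstream of
    each gene, and repeat/centromere intervals. Intervals extending beyond a
    chromosome end are clipped with a warning.
    """
    mask = {c: np.ones(L, dtype=bool) for c, L in chrom_lengths.items()}
    if gff is not None:
        df = _read_gff_df(gff)
        genes = df[df.Feature == "gene"]
        if genes.empty:
            genes = df[df.Feature == "mRNA"]
        for _, g in genes.iterrows():
            if g.Chromosome not in mask:
                continue
            arr = mask[g.Chromosome]
            s = max(0, int(g.Start) - flank)
            e = int(g.End) + flank
            if e > len(arr):
                warnings.warn(f"gene interval on {g.Chromosome} extends past "
                              "chromosome end; clipped")
                e = len(arr)
            arr[s:e] = False
    if repeat_bed is not None:
        rep = _read_bed_df(repeat_bed)
        for _, r in rep.iterrows():
            if r.Chromosome not in mask:
                continue
            arr = mask[r.Chromosome]
            e = int(r.End)
            if e > len(arr):
                warnings.warn(f"repeat interval on {r.Chromosome} extends "
                              "past chromosome end; clipped")
                e = len(arr)
            arr[int(r.Start):e] = False
    return AccessibilityMask(mask)
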
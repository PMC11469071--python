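"""Synthetic datasets with the statistical structure the pipeline assumes.

The default study design emulates a westward serial-founder expansion of
nine demes (six dimorphic heterostylous, two trimorphic, one monomorphic
homostylous; 105 diploid individuals in total) across 11 chromosomes.
Each deme west of the origin is founded by a split with a transient founder
bottleneck; the homostyly shift is emulated as a recent contraction plus
elevated inbreeding (selfing stand-in) in the homostyle-bearing demes.
Nonsynonymous (0-fold) sites are thinned according to a gamma DFE so that
purifying selection leaves its footprint in the selected spectrum. VCF
quality annotations are drawn from simple calibrated distributions solely
to exercise the filter cascade; they carry no read-level realism.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .coalsim import (DemographicModel, Population, SampleConfig, SizeChange,
                      Split, drop_mutations, haplotypes_to_diploids,
                      simulate_genealogy)
from .dfe_fit import _dfe_expected_selected, _sojourn_H
from .io_preprocess import GenotypeMatrix, VariantRecord, write_vcf
from .sfs_tools import SFS1D

__all__ = ["DemeSpec", "StudyDesign", "generate_dataset", "generate_block_ld",
           "sample_sfs_pair"]

NUCLEOTIDES = np.array(list("ACGT"))


@dataclass
class DemeSpec:
    name: str
    n_individuals: int
    kind: str                 # dimorphic | trimorphic | monomorphic
    current_ne: float
    split_time: float | None  # generations ago it split from its parent
    parent: str | None
    inbreeding: float = 0.0


def _default_demes() -> list[DemeSpec]:
    # scaled sizes (thousands) keep desk runs fast while preserving the
    # east-to-west diversity gradient; F defaults: 0.45 trimorphic,
    # 0.9 monomorphic
    return [
        DemeSpec("TR-D", 12, "dimorphic", 12_000, None, None),
        DemeSpec("SK-D", 12, "dimorphic", 10_000, 8_000, "TR-D"),
        DemeSpec("CH-D", 12, "dimorphic", 9_000, 7_000, "SK-D"),
        DemeSpec("EN1-D", 12, "dimorphic", 8_000, 6_000, "CH-D"),
        DemeSpec("EN2-D", 12, "dimorphic", 7_000, 5_000, "EN1-D"),
        DemeSpec("EN3-D", 12, "dimorphic", 6_000, 4_000, "EN2-D"),
        DemeSpec("EN4-T", 12, "trimorphic", 5_000, 3_000, "EN3-D", 0.45),
        DemeSpec("EN5-T", 12, "trimorphic", 4_500, 2_000, "EN4-T", 0.45),
        DemeSpec("EN6-M", 9, "monomorphic", 1_500, 1_000, "EN5-T", 0.90),
    ]


@dataclass
class StudyDesign:
    """Generating parameters of a full synthetic dataset."""

    demes: list[DemeSpec] = field(default_factory=_default_demes)
    founder_bottleneck_size: float = 300.0
    founder_bottleneck_duration: float = 200.0
    n_chromosomes: int = 11
    chromosome_length: int = 150_000
    gene_length: int = 3_000
    gene_spacing: int = 15_000
    repeat_fraction_center: float = 0.10   # centromere-like block per chrom
    mutation_rate: float = 1.23e-8
    dfe_shape: float = 0.3
    dfe_mean_nes: float = 300.0
    mean_depth: float = 18.9
    te_noise_sd: float = 0.05
    te_base_content: Mapping[str, float] = field(default_factory=lambda: {
        "CACTA": 1.2, "hAT": 0.8, "Helitron": 1.5, "Mutator": 0.9,
        "PIF-Harbinger": 0.5, "Tc1-Mariner": 0.4, "LTR/Copia": 2.5,
        "LTR/Gypsy": 3.5})
    te_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    te_coverage: Mapping[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        names = [d.name for d in self.demes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate deme names")
        for d in self.demes[1:]:
            if d.parent not in names:
                raise ValueError(f"deme {d.name} has unknown parent")
            if d.split_time is None or d.split_time <= 0:
                raise ValueError(f"deme {d.name} needs a positive split time")

    def total_individuals(self) -> int:
        return sum(d.n_individuals for d in self.demes)

    def demographic_model(self) -> DemographicModel:
        """Backward-in-time serial-founder model implied by the design."""
        self.validate()
        pops = [Population(d.name, d.current_ne) for d in self.demes]
        events: list[Split | SizeChange] = []
        for d in self.demes:
            if d.parent is None:
                continue
            t_bot = d.split_time - self.founder_bottleneck_duration
            if t_bot > 0:
                events.append(SizeChange(t_bot, d.name,
                                         self.founder_bottleneck_size))
            events.append(Split(d.split_time, d.name, d.parent))
        model = DemographicModel(populations=pops, events=events,
                                 mutation_rate=self.mutation_rate)
        model.validate()
        return model

    def sample_config(self, L: int) -> SampleConfig:
        return SampleConfig(
            n_per_pop={d.name: 2 * d.n_individuals for d in self.demes},
            L=L,
            inbreeding={d.name: d.inbreeding for d in self.demes})


def _morph_labels(design: StudyDesign) -> list[str]:
    labels = []
    for d in design.demes:
        if d.kind == "dimorphic":
            half = d.n_individuals // 2
            lab = ["S"] * half + ["L"] * (d.n_individuals - half)
        elif d.kind == "trimorphic":
            third = d.n_individuals // 3
            lab = (["S"] * third + ["L"] * third
                   + ["H"] * (d.n_individuals - 2 * third))
        else:
            lab = ["H"] * d.n_individuals
        labels.extend(lab)
    return labels


def _selection_thinning(dosages: np.ndarray, nes: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    """Keep-probability thinning of selected sites.

    A site at sample derived frequency x under scaled selection
    gamma = 4 N_e s is retained with probability proportional to
    H(gamma, x) / H(0, x), the sojourn-density ratio to neutrality.
    Returns a boolean keep mask."""
    n_hap = 2 * dosages.shape[0]
    freq = np.clip(dosages.sum(axis=0) / n_hap, 1.0 / n_hap,
                   1 - 1.0 / n_hap)
    gam = np.minimum(4.0 * nes, 1e8)
    ratios = np.empty(len(freq))
    for j in range(len(freq)):
        H = _sojourn_H(np.array([gam[j]]), np.array([freq[j]]))[0, 0]
        ratios[j] = H * freq[j] / 2.0
    ratios = ratios / max(ratios.max(), 1.0)
    return rng.random(len(ratios)) < ratios


def _synthetic_gff(design: StudyDesign) -> tuple[str, list[dict]]:
    """GFF3 text plus a per-gene record list for one genome layout."""
    lines = ["##gff-version 3"]
    genes = []
    gid = 0
    for c in range(design.n_chromosomes):
        chrom = f"chr{c + 1}"
        start = design.gene_spacing // 2
        while start + design.gene_length < design.chromosome_length:
            gid += 1
            strand = "+" if gid % 2 else "-"
            s1, e1 = start + 1, start + design.gene_length  # GFF 1-based
            lines.append(f"{chrom}\tsynth\tgene\t{s1}\t{e1}\t.\t{strand}\t.\t"
                         f"ID=gene{gid}")
            lines.append(f"{chrom}\tsynth\tmRNA\t{s1}\t{e1}\t.\t{strand}\t.\t"
                         f"ID=mrna{gid};Parent=gene{gid}")
            lines.append(f"{chrom}\tsynth\tCDS\t{s1}\t{e1}\t.\t{strand}\t0\t"
                         f"ID=cds{gid};Parent=mrna{gid}")
            genes.append({"chrom": chrom, "start": start,
                          "end": start + design.gene_length,
                          "strand": strand})
            start += design.gene_spacing
    return "\n".join(lines) + "\n", genes


def _repeat_bed(design: StudyDesign) -> tuple[str, list[tuple[str, int, int]]]:
    rows = []
    half = design.repeat_fraction_center / 2
    for c in range(design.n_chromosomes):
        chrom = f"chr{c + 1}"
        mid = design.chromosome_length // 2
        s = int(mid - half * design.chromosome_length)
        e = int(mid + half * design.chromosome_length)
        rows.append((chrom, s, e))
    text = "\n".join(f"{c}\t{s}\t{e}" for c, s, e in rows) + "\n"
    return text, rows


def _degeneracy_of_offset(offset_in_gene: int, strand: str,
                          gene_length: int) -> str:
    """Site class of a position inside a synthetic single-exon CDS.

    The generator does not materialize real codon sequences for variant
    placement; it stylizes degeneracy by reading frame: third codon
    positions act as 4-fold (synonymous), first and second as 0-fold.
    """
    off = offset_in_gene if strand == "+" else gene_length - 1 - offset_in_gene
    return "4fold" if off % 3 == 2 else "0fold"


def generate_dataset(design: StudyDesign | None = None, seed: int = 0,
                     out_dir: str | None = None) -> dict:
    """Generate a full synthetic dataset.

    Returns a dict with the genotype matrix, per-site records, GFF3/BED
    text, the ancestral-allele table, the TE depth table, and a truth
    record storing every generating parameter; with ``out_dir`` set, the
    same content is written as VCF / GFF3 / BED / TSV / JSON files.
    Outputs are byte-identical under the same seed.
    """
    design = design or StudyDesign()
    design.validate()
    rng = np.random.default_rng(seed)
    model = design.demographic_model()
    L = design.chromosome_length
    config = design.sample_config(L)
    gff_text, genes = _synthetic_gff(design)
    rep_text, repeats = _repeat_bed(design)

    gene_lookup: dict[str, list[dict]] = {}
    for g in genes:
        gene_lookup.setdefault(g["chrom"], []).append(g)

    samples, pops_of, morphs = [], [], _morph_labels(design)
    for d in design.demes:
        for i in range(d.n_individuals):
            samples.append(f"{d.name}_{i + 1:02d}")
            pops_of.append(d.name)

    all_chrom, all_pos, all_ref, all_alt = [], [], [], []
    all_calls = []
    site_class_list = []
    truth_site_counts = {"neutral": 0, "0fold_kept": 0, "0fold_removed": 0,
                         "4fold": 0}
    for c in range(design.n_chromosomes):
        chrom = f"chr{c + 1}"
        gen = simulate_genealogy(model, config, rng)
        positions, hap = drop_mutations(gen, design.mutation_rate, L, rng)
        if len(positions) == 0:
            continue
        dosage = haplotypes_to_diploids(hap, gen.leaf_pops, gen.pop_names,
                                        config.inbreeding, rng)
        # classify sites by the synthetic annotation
        classes = np.empty(len(positions), dtype=object)
        classes[:] = "neutral"
        for g in gene_lookup.get(chrom, []):
            inside = (positions >= g["start"]) & (positions < g["end"])
            for j in np.flatnonzero(inside):
                classes[j] = _degeneracy_of_offset(
                    int(positions[j] - g["start"]), g["strand"],
                    design.gene_length)
        keep = np.ones(len(positions), dtype=bool)
        sel = np.flatnonzero(classes == "0fold")
        if len(sel):
            nes = rng.gamma(design.dfe_shape,
                            design.dfe_mean_nes / design.dfe_shape,
                            size=len(sel))
            kept_mask = _selection_thinning(dosage[:, sel], nes, rng)
            keep[sel[~kept_mask]] = False
            truth_site_counts["0fold_kept"] += int(kept_mask.sum())
            truth_site_counts["0fold_removed"] += int((~kept_mask).sum())
        truth_site_counts["neutral"] += int((classes == "neutral").sum())
        truth_site_counts["4fold"] += int((classes == "4fold").sum())
        positions, dosage, classes = (positions[keep], dosage[:, keep],
                                      classes[keep])
        ref = rng.choice(NUCLEOTIDES, size=len(positions))
        shift = rng.integers(1, 4, size=len(positions))
        alt = NUCLEOTIDES[(np.searchsorted(NUCLEOTIDES, ref) + shift) % 4]
        all_chrom.extend([chrom] * len(positions))
        all_pos.append(positions)
        all_ref.append(ref)
        all_alt.append(alt)
        all_calls.append(dosage)
        site_class_list.extend(classes.tolist())

    matrix = GenotypeMatrix(
        samples=samples,
        chrom=np.array(all_chrom, dtype=object),
        pos=np.concatenate(all_pos) if all_pos else np.zeros(0, dtype=np.int64),
        ref=np.concatenate(all_ref).astype(object),
        alt=np.concatenate(all_alt).astype(object),
        calls=np.hstack(all_calls) if all_calls else
        np.zeros((len(samples), 0), dtype=np.int8),
        populations=pops_of, morphs=morphs)

    records = _calibrated_records(matrix, design, rng)
    te_table = _te_depth_table(design, samples, pops_of, morphs, rng)

    truth = {
        "seed": seed,
        "demes": [asdict(d) for d in design.demes],
        "founder_bottleneck": {"size": design.founder_bottleneck_size,
                               "duration": design.founder_bottleneck_duration},
        "mutation_rate": design.mutation_rate,
        "dfe": {"shape": design.dfe_shape, "mean_nes": design.dfe_mean_nes},
        "te_effects": {f"{p}|{s}": v
                       for (p, s), v in design.te_effects.items()},
        "te_base_content": dict(design.te_base_content),
        "site_counts": truth_site_counts,
        "n_variants": int(matrix.n_sites),
    }

    out = {
        "matrix": matrix,
        "records": records,
        "site_classes": np.array(site_class_list, dtype=object),
        "gff3": gff_text,
        "repeats_bed": rep_text,
        "te_table": te_table,
        "truth": truth,
        "chrom_lengths": {f"chr{c + 1}": L
                          for c in range(design.n_chromosomes)},
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_vcf(matrix, os.path.join(out_dir, "variants.vcf"),
                  records=records, contig_lengths=out["chrom_lengths"])
        with open(os.path.join(out_dir, "annotation.gff3"), "w") as fh:
            fh.write(gff_text)
        with open(os.path.join(out_dir, "repeats.bed"), "w") as fh:
            fh.write(rep_text)
        with open(os.path.join(out_dir, "ancestral.tsv"), "w") as fh:
            fh.write("chrom\tpos\tancestral\n")
            for ch, p, r in zip(matrix.chrom, matrix.pos, matrix.ref):
                fh.write(f"{ch}\t{int(p) + 1}\t{r}\n")
        te_table.to_csv(os.path.join(out_dir, "te_depth.tsv"), sep="\t",
                        index=False)
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return out


def _calibrated_records(matrix: GenotypeMatrix, design: StudyDesign,
                        rng: np.random.Generator) -> list[VariantRecord]:
    """Draw VCF quality annotations from simple calibrated distributions."""
    n_ind = matrix.n_samples
    records = []
    for j in range(matrix.n_sites):
        depths = rng.poisson(design.mean_depth, size=n_ind)
        g = matrix.calls[:, j]
        ad = np.zeros((n_ind, 2), dtype=np.int32)
        alt_reads = np.where(
            g == 1, rng.binomial(np.maximum(depths, 1), 0.5),
            np.where(g == 2, depths, 0))
        ad[:, 1] = alt_reads
        ad[:, 0] = depths - alt_reads
        records.append(VariantRecord(
            chrom=matrix.chrom[j], pos=int(matrix.pos[j]) + 1,
            ref=str(matrix.ref[j]), alt=str(matrix.alt[j]),
            qd=float(np.clip(rng.normal(20, 5), 0.1, None)),
            mq=float(np.clip(rng.normal(55, 3), 1, None)),
            fs=float(rng.exponential(3.0)),
            mq_rank_sum=float(rng.normal(0, 1)),
            read_pos_rank_sum=float(rng.normal(0, 1)),
            dp=float(depths.sum()),
            inbreeding_coeff=float(np.clip(rng.normal(0.05, 0.1), -1, 1)),
            ad=ad))
    return records


def _te_depth_table(design: StudyDesign, samples: Sequence[str],
                    pops_of: Sequence[str], morphs: Sequence[str],
                    rng: np.random.Generator):
    import pandas as pd

    rows = []
    for ind, pop, morph in zip(samples, pops_of, morphs):
        genome_depth = max(rng.normal(design.mean_depth, 3.0), 1.0)
        for sf, base in design.te_base_content.items():
            effect = design.te_effects.get((pop, sf), 0.0)
            content = max(base * (1.0 + effect)
                          + rng.normal(0.0, design.te_noise_sd), 0.0)
            cov = design.te_coverage.get(sf, 0.95)
            rows.append({"individual": ind, "population": pop,
                         "morph": morph, "superfamily": sf,
                         "te_depth": content * genome_depth,
                         "genome_depth": genome_depth,
                         "coverage": cov})
    return pd.DataFrame(rows)


def generate_block_ld(matrix: GenotypeMatrix, block_bp: float, rho: float,
                      seed: int) -> GenotypeMatrix:
    """Impose distance-decaying genotype correlation by site chaining.

    Each site's dosage vector is, per individual, copied from the previous
    site with probability rho ** (distance / block_bp) and otherwise kept as
    the site's own (independent) dosage, producing within-chromosome
    correlation that decays approximately geometrically with distance.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    calls = matrix.calls.copy()
    for chrom in dict.fromkeys(matrix.chrom.tolist()):
        idx = np.flatnonzero(matrix.chrom == chrom)
        for a, b in zip(idx[:-1], idx[1:]):
            if rho == 0:
                break
            d = float(matrix.pos[b] - matrix.pos[a])
            c = rho ** (d / block_bp)
            copy = rng.random(matrix.n_samples) < c
            calls[copy, b] = calls[copy, a]
    out = GenotypeMatrix(samples=matrix.samples, chrom=matrix.chrom,
                         pos=matrix.pos, ref=matrix.ref, alt=matrix.alt,
                         calls=calls, populations=matrix.populations,
                         morphs=matrix.morphs)
    return out


def sample_sfs_pair(n: int, theta_neutral: float, theta_selected: float,
                    shape: float, mean_nes: float, seed: int
                    ) -> tuple[SFS1D, SFS1D]:
    """Draw a matched neutral/selected SFS pair from their mutational
    opportunities.

    ``theta_neutral`` and ``theta_selected`` are the population-scaled
    mutation rates of the two site blocks (theta per site x block length),
    so the *number* of selected SNPs carries the purifying-selection
    deficit. Neutral counts are Poisson with mean theta/i; selected counts
    Poisson with the gamma-DFE expectation — the ground truth for
    DFE-recovery experiments (the mutational-target ratio is
    ``theta_selected / theta_neutral``).
    """
    rng = np.random.default_rng(seed)
    i = np.arange(1, n)
    xi_neu = rng.poisson(theta_neutral / i).astype(float)
    e_sel = _dfe_expected_selected(shape, mean_nes, n)
    xi_sel = rng.poisson(theta_selected * e_sel).astype(float)
    return SFS1D(n=n, xi=xi_neu), SFS1D(n=n, xi=xi_sel)
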
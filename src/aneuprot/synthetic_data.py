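"""Synthetic disome-study generator with known ground truth.

Emulates the statistical structure of quantitative proteomics of haploid
yeast strains carrying one extra chromosome ("disomes"): genes on the
duplicated chromosome rise ~twofold (log2 ratio ~1.0) except for a
dosage-compensated ("attenuated") subset concentrated in protein-complex
subunits, plus a small aneuploidy-associated protein signature (APS) whose
per-strain shift scales with the size of the extra chromosome, and an
environmental-stress-response (ESR) component shared by all layers.

Defaults encode the stated study conditions: measurement noise SD 0.2 on
the log2 scale for the rich-medium/TMT-like condition and 0.35 for the
synthetic-medium/SILAC-like condition; full-dosage mean 1.0 and attenuated
mean 0.66 (~1.6-fold); 33% of genes in complexes with a 79-member
ribosome-like complex; half of duplicated complex members attenuated; 12
disomic strains covering chromosomes 1, 2, 5, 8-16.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    ComplexCatalog,
    GeneAnnotation,
    QuantMatrix,
    chromosome_name,
    write_annotation,
    write_complex_catalog,
    write_gene_sets,
    write_quant_matrix,
)

#: chromosomes duplicated in the 12 disomic strains under study
DEFAULT_DISOME_CHROMOSOMES: tuple[int, ...] = (1, 2, 5, 8, 9, 10, 11, 12, 13, 14, 15, 16)

#: log2 shifts applied to the ESR gene sets at esr_scale = 1
ESR_UP_SHIFT = 0.4
ESR_DOWN_SHIFT = -0.6


@dataclass
class GenomeModel:
    """A yeast-like genome: genes on chromosomes plus a complex catalog."""

    annotation: GeneAnnotation
    complex_catalog: ComplexCatalog
    complex_fraction: float
    ribosomal_set: set[str] = field(default_factory=set)
    esr_up: set[str] = field(default_factory=set)
    esr_down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        genes = set(self.annotation.genes)
        members = self.complex_catalog.members()
        if not members <= genes:
            raise ValueError("complex catalog references unknown genes")
        if self.n_genes and abs(len(members) / self.n_genes - self.complex_fraction) > 0.02:
            raise ValueError(
                "complex membership fraction deviates from complex_fraction by > 0.02"
            )

    @property
    def n_genes(self) -> int:
        return len(self.annotation.genes)

    @property
    def genes(self) -> list[str]:
        return self.annotation.genes

    def chromosome_sizes(self) -> dict[str, int]:
        return {k: int(v) for k, v in self.annotation.chromosome_sizes().items()}

    def genes_on(self, chromosome: str) -> list[str]:
        return self.annotation.genes_on(chromosome)


@dataclass
class DisomeTruth:
    """Generative truth for one disomic strain."""

    duplicated_chromosome: str
    attenuated_genes: set[str]
    mu_full: float = 1.0
    mu_att: float = 0.46
    noise_sd: float = 0.2
    aps_genes: set[str] = field(default_factory=set)
    aps_coefficient: float = 0.0
    esr_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mu_att >= self.mu_full:
            raise ValueError("attenuated mean must lie below the full-dosage mean")

    def validate_against(self, genome: GenomeModel) -> None:
        on_dup = set(genome.genes_on(self.duplicated_chromosome))
        if not on_dup:
            raise ValueError(f"unknown chromosome {self.duplicated_chromosome!r}")
        if not self.attenuated_genes <= on_dup:
            raise ValueError("attenuated genes must lie on the duplicated chromosome")


def generate_genome(
    n_genes: int = 4800,
    n_chromosomes: int = 16,
    complex_fraction: float = 0.33,
    seed: int = 0,
    chromosome_sizes: Sequence[int] | None = None,
    esr_up_size: int = 300,
    esr_down_size: int = 600,
) -> GenomeModel:
    """Generate a genome with chromosomes spanning a ~3-fold size range.

    Complexes are disjoint gene sets of size 2-80; when the membership
    budget allows, one ribosome-like complex of 79 genes is created and
    doubles as the ribosomal gene set.
    """
    if n_genes <= 0 or n_chromosomes <= 0:
        raise ValueError("n_genes and n_chromosomes must be positive")
    if n_genes < n_chromosomes:
        raise ValueError("need at least one gene per chromosome")
    if not 0.0 <= complex_fraction <= 1.0:
        raise ValueError("complex_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    if chromosome_sizes is None:
        weights = np.linspace(1.0, 3.0, n_chromosomes)
        rng.shuffle(weights)
        ideal = n_genes * weights / weights.sum()
        sizes = np.maximum(1, np.floor(ideal).astype(int))
        # largest-remainder rounding so sizes sum exactly to n_genes
        order = np.argsort(ideal - np.floor(ideal))[::-1]
        for idx in np.tile(order, 2):
            if sizes.sum() == n_genes:
                break
            sizes[idx] += 1 if sizes.sum() < n_genes else -1
    else:
        sizes = np.asarray(chromosome_sizes, dtype=int)
        if len(sizes) != n_chromosomes or sizes.sum() != n_genes:
            raise ValueError("explicit chromosome sizes must sum to n_genes")

    width = max(4, len(str(n_genes)))
    genes = [f"g{i:0{width}d}" for i in range(1, n_genes + 1)]
    chroms: list[str] = []
    positions: list[int] = []
    for c, size in enumerate(sizes, start=1):
        chroms.extend([chromosome_name(c)] * int(size))
        positions.extend(range(int(size)))
    table = pd.DataFrame(
        {"chromosome": chroms, "position": positions}, index=pd.Index(genes, name="gene")
    )

    target = int(round(complex_fraction * n_genes))
    pool = list(rng.permutation(genes))
    complexes: dict[str, list[str]] = {}
    ribosomal: set[str] = set()
    assigned = 0
    if target - assigned >= 79:
        members = [pool.pop() for _ in range(79)]
        complexes["ribosome"] = members
        ribosomal = set(members)
        assigned += 79
    i = 1
    while target - assigned >= 2:
        size = int(min(rng.integers(2, 81), target - assigned))
        if size < 2:
            break
        complexes[f"cpx{i:04d}"] = [pool.pop() for _ in range(size)]
        assigned += size
        i += 1

    annotation = GeneAnnotation(table)
    catalog = ComplexCatalog(complexes, provenance="synthetic")
    remaining = [g for g in genes if g not in catalog.members()]
    esr_pool = list(rng.permutation(remaining))
    esr_up = set(esr_pool[: min(esr_up_size, len(esr_pool) // 4)])
    esr_down = set(esr_pool[len(esr_pool) // 4:][: min(esr_down_size, len(esr_pool) // 4)])
    annotation.gene_sets = {
        "ribosomal": set(ribosomal),
        "esr_up": esr_up,
        "esr_down": esr_down,
    }
    return GenomeModel(
        annotation=annotation,
        complex_catalog=catalog,
        complex_fraction=complex_fraction,
        ribosomal_set=ribosomal,
        esr_up=esr_up,
        esr_down=esr_down,
    )


def complex_attenuation_roles(
    genome: GenomeModel,
    attenuated_complex_fraction: float = 0.5,
    seed: int = 0,
) -> set[str]:
    """Decide, genome-wide, which complex subunits are attenuation-prone.

    Attenuation is coherent within complexes: about half of all complexes
    are "attenuated-type" — every subunit unstable except one stable
    scaffold — while the rest keep exactly one unstable subunit. The
    ribosome-like complex is fully unstable (no scaffold), mirroring the
    ribosome and nucleosome as the complexes without any stable subunit.
    The aggregate comes out near half of all complex members.
    """
    if attenuated_complex_fraction <= 0:
        return set()
    rng = np.random.default_rng((seed, 7))
    prone: set[str] = set()
    for cid, members in genome.complex_catalog.complexes.items():
        if cid == "ribosome":
            prone.update(members)
            continue
        if rng.random() < attenuated_complex_fraction:
            scaffold = members[int(rng.integers(len(members)))]
            prone.update(g for g in members if g != scaffold)
        else:
            prone.add(members[int(rng.integers(len(members)))])
    return prone


def default_disome_truth(
    genome: GenomeModel,
    chromosome: str,
    mu_full: float = 1.0,
    mu_att: float = 0.46,
    noise_sd: float = 0.2,
    attenuated_complex_fraction: float = 0.5,
    attenuated_noncomplex_fraction: float = 88 / 1650,
    aps_genes: set[str] | None = None,
    aps_coefficient: float = 0.0,
    esr_scale: float = 0.0,
    seed: int = 0,
    prone: set[str] | None = None,
) -> DisomeTruth:
    """Plant attenuation on a duplicated chromosome, biased toward complexes.

    Complex-subunit attenuation follows genome-wide per-complex roles (see
    :func:`complex_attenuation_roles`), so the same complex behaves
    consistently in every strain; the non-complex attenuation rate defaults
    to ~88/1650 so a 12-strain study carries ~88 attenuated proteins
    outside complexes.
    """
    rng = np.random.default_rng((seed, int(chromosome[3:])))
    on_dup = genome.genes_on(chromosome)
    members = genome.complex_catalog.members()
    dup_free = [g for g in on_dup if g not in members]
    if prone is None:
        prone = complex_attenuation_roles(genome, attenuated_complex_fraction, seed)
    attenuated: set[str] = set(g for g in on_dup if g in prone)
    n_free = int(round(attenuated_noncomplex_fraction * len(dup_free)))
    if n_free:
        attenuated.update(rng.choice(dup_free, size=n_free, replace=False))
    return DisomeTruth(
        duplicated_chromosome=chromosome,
        attenuated_genes=attenuated,
        mu_full=mu_full,
        mu_att=mu_att,
        noise_sd=noise_sd,
        aps_genes=set(aps_genes or ()),
        aps_coefficient=aps_coefficient,
        esr_scale=esr_scale,
    )


def _mean_profile(genome: GenomeModel, truth: DisomeTruth, layer: str) -> pd.Series:
    """Noise-free expected log2 ratio per gene for one strain/layer.

    Attenuation and the APS act only on the protein layer (transcripts of
    attenuated genes rise ~twofold with no compensation); ESR shifts apply
    to every layer.
    """
    if layer not in ("protein", "mRNA", "footprint"):
        raise ValueError(f"unknown layer {layer!r}")
    truth.validate_against(genome)
    mu = pd.Series(0.0, index=pd.Index(genome.genes, name="gene"))
    on_dup = genome.genes_on(truth.duplicated_chromosome)
    mu.loc[on_dup] = truth.mu_full
    if layer == "protein":
        if truth.attenuated_genes:
            mu.loc[sorted(truth.attenuated_genes)] = truth.mu_att
        if truth.aps_genes and truth.aps_coefficient:
            shift = truth.aps_coefficient * len(on_dup)
            mu.loc[sorted(truth.aps_genes)] += shift
    if truth.esr_scale:
        if genome.esr_up:
            mu.loc[sorted(genome.esr_up)] += ESR_UP_SHIFT * truth.esr_scale
        if genome.esr_down:
            mu.loc[sorted(genome.esr_down)] += ESR_DOWN_SHIFT * truth.esr_scale
    return mu


def generate_disome_matrix(
    genome: GenomeModel,
    truth: DisomeTruth,
    layer: str = "protein",
    seed: int = 0,
    strain: str | None = None,
    condition: str = "",
) -> QuantMatrix:
    """One strain column: expected profile plus additive N(0, noise_sd) noise."""
    mu = _mean_profile(genome, truth, layer)
    rng = np.random.default_rng(seed)
    values = mu.to_numpy()
    if truth.noise_sd > 0:
        values = values + rng.normal(0.0, truth.noise_sd, size=len(mu))
    if strain is None:
        strain = f"disome{int(truth.duplicated_chromosome[3:]):02d}"
    frame = pd.DataFrame({strain: values}, index=mu.index)
    return QuantMatrix(frame, layer=layer, condition=condition)


def generate_wt_column(
    genome: GenomeModel, noise_sd: float, seed: int = 0, strain: str = "wt"
) -> QuantMatrix:
    """Wild-type/wild-type control column: pure measurement noise."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {strain: rng.normal(0.0, noise_sd, size=genome.n_genes)},
        index=pd.Index(genome.genes, name="gene"),
    )
    return QuantMatrix(frame, layer="protein", condition="control")


# ---------------------------------------------------------------------------
# peptide tables


def generate_peptide_table(
    protein_truth: Mapping[str, float],
    peptides_per_protein: int | Callable[[np.random.Generator], int] = 8,
    platform: str = "SILAC",
    seed: int = 0,
    noise_sd: float = 0.0,
    bad_fraction: float = 0.0,
) -> pd.DataFrame:
    """Peptide-level table encoding planted protein log2 ratios.

    SILAC rows carry heavy/light signal-to-noise and a heavy/light ratio
    with multiplicative (log-normal) noise; TMT rows carry six reporter
    intensities divided by a per-scan ion accumulation time (so that
    denormalization restores the planted intensities). A ``planted_bad``
    column marks rows deliberately planted below the platform's
    signal-to-noise / intensity filters.
    """
    if not protein_truth:
        raise ValueError("protein_truth must not be empty")
    if platform not in ("SILAC", "TMT"):
        raise ValueError(f"unknown platform {platform!r}")
    rng = np.random.default_rng(seed)
    rows = []
    pep_i = 0
    for protein, log2_ratio in protein_truth.items():
        k = peptides_per_protein(rng) if callable(peptides_per_protein) else peptides_per_protein
        if k < 1:
            raise ValueError("peptides_per_protein must be >= 1")
        for _ in range(k):
            pep_i += 1
            bad = bool(rng.random() < bad_fraction)
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            if platform == "SILAC":
                ratio = 2.0 ** (log2_ratio + noise)
                if bad:
                    # fails both clauses: both s2n < 2 and max < 5
                    s2n_l = rng.uniform(0.1, 1.9)
                    s2n_h = rng.uniform(0.1, 1.9)
                else:
                    s2n_l = rng.uniform(5.0, 50.0)
                    s2n_h = s2n_l * ratio
                rows.append(
                    (f"pep{pep_i:06d}", protein, s2n_h, s2n_l, ratio, bad)
                )
            else:
                acc_time = rng.uniform(0.5, 2.0)
                base = 20.0 if bad else rng.uniform(100.0, 1000.0)
                denorm = np.empty(6)
                denorm[0] = base
                denorm[1:] = base * 2.0 ** (log2_ratio + noise)
                if bad:
                    # zero-channel intensity below the >= 20 rule
                    denorm[0] = rng.uniform(1.0, 19.0)
                    denorm[1:] = rng.uniform(1.0, 19.0, size=5)
                stored = denorm / acc_time
                rows.append(
                    (f"pep{pep_i:06d}", protein, *stored, acc_time, bad)
                )
    if platform == "SILAC":
        cols = ["peptide", "protein", "s2n_heavy", "s2n_light", "ratio_hl", "planted_bad"]
    else:
        cols = (
            ["peptide", "protein"]
            + [f"intensity_{i}" for i in range(6)]
            + ["accumulation_time", "planted_bad"]
        )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# turnover timecourses


def default_turnover_slopes(
    genome: GenomeModel, truth: DisomeTruth, slope: float = 4.8e-4
) -> dict[str, float]:
    """Positive turnover-inhibition slopes for attenuated duplicated genes.

    Attenuated proteins are translated in excess and rapidly degraded, so
    blocking degradation makes them accumulate; everything else stays flat.
    The default slope gives ~+0.14 log2 (~10%) over 300 s.
    """
    return {g: (slope if g in truth.attenuated_genes else 0.0) for g in genome.genes}


def generate_turnover_truth(
    genome: GenomeModel,
    truth: DisomeTruth,
    slopes: Mapping[str, float],
    timepoints: Sequence[float] = (0.0, 90.0, 300.0),
    seed: int = 0,
    noise_sd: float = 0.1,
) -> QuantMatrix:
    """Timecourse columns: baseline disome profile + slope x t + noise."""
    timepoints = list(timepoints)
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must be strictly increasing")
    baseline = _mean_profile(genome, truth, "protein")
    slope_vec = pd.Series(
        [float(slopes.get(g, 0.0)) for g in genome.genes], index=baseline.index
    )
    rng = np.random.default_rng(seed)
    data = {}
    for t in timepoints:
        col = baseline + slope_vec * t
        if noise_sd > 0:
            col = col + rng.normal(0.0, noise_sd, size=len(col))
        data[f"t{int(t)}"] = col
    return QuantMatrix(pd.DataFrame(data), layer="protein", condition="turnover")


# ---------------------------------------------------------------------------
# full multi-strain studies


@dataclass
class SyntheticStudy:
    """A complete generated study: matrices, truths, annotation, catalog."""

    genome: GenomeModel
    truths: dict[str, DisomeTruth]
    protein: QuantMatrix
    mrna: QuantMatrix
    condition: str

    @property
    def annotation(self) -> GeneAnnotation:
        return self.genome.annotation

    @property
    def catalog(self) -> ComplexCatalog:
        return self.genome.complex_catalog

    def duplicated_map(self) -> dict[str, str]:
        return {s: t.duplicated_chromosome for s, t in self.truths.items()}

    def attenuated_truth(self) -> set[str]:
        out: set[str] = set()
        for t in self.truths.values():
            out |= t.attenuated_genes
        return out

    def aps_genes(self) -> set[str]:
        for t in self.truths.values():
            return set(t.aps_genes)
        return set()

    def write(self, directory: str | Path) -> None:
        """Materialize the study as the TSV formats the readers consume."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_quant_matrix(self.protein, directory / "protein.tsv")
        write_quant_matrix(self.mrna, directory / "mrna.tsv")
        write_annotation(self.annotation, directory / "annotation.tsv")
        write_complex_catalog(self.catalog, directory / "complexes.tsv")
        sets = {k: sorted(v) for k, v in self.annotation.gene_sets.items() if v}
        aps = self.aps_genes()
        if aps:
            sets["aps_truth"] = sorted(aps)
        sets["attenuated_truth"] = sorted(self.attenuated_truth())
        write_gene_sets(sets, directory / "gene_sets.tsv")


def generate_study(
    genome: GenomeModel | None = None,
    disome_chromosomes: Sequence[int] = DEFAULT_DISOME_CHROMOSOMES,
    condition: str = "YEPD",
    mu_full: float = 1.0,
    mu_att: float = 0.46,
    noise_sd: float | None = None,
    attenuated_complex_fraction: float = 0.5,
    attenuated_noncomplex_fraction: float = 88 / 1650,
    n_aps_genes: int = 92,
    aps_min_shift: float = 0.4,
    esr_scale: float | None = None,
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a 12-disome study with protein and mRNA layers.

    ``condition="YEPD"`` (rich medium, TMT-like) uses noise SD 0.2, carries
    the APS (with the smallest duplicated chromosome shifted by
    ``aps_min_shift``) and a damped ESR (scale 0.3). ``condition="synthetic"``
    (SILAC-like) uses noise SD 0.35, a full-strength ESR, and no APS — the
    signature is only detectable in rich medium.
    """
    if condition == "YEPD":
        noise_sd = 0.2 if noise_sd is None else noise_sd
        esr_scale = 0.3 if esr_scale is None else esr_scale
        with_aps = True
    elif condition == "synthetic":
        noise_sd = 0.35 if noise_sd is None else noise_sd
        esr_scale = 1.0 if esr_scale is None else esr_scale
        with_aps = False
    else:
        raise ValueError(f"unknown condition {condition!r}; use 'YEPD' or 'synthetic'")
    if genome is None:
        genome = generate_genome(seed=seed)

    rng = np.random.default_rng((seed, 9001))
    sizes = genome.chromosome_sizes()
    dup_chroms = [chromosome_name(c) for c in disome_chromosomes]
    missing = [c for c in dup_chroms if c not in sizes]
    if missing:
        raise ValueError(f"genome lacks chromosomes {missing}")

    aps_genes: set[str] = set()
    aps_coefficient = 0.0
    if with_aps and n_aps_genes > 0:
        non_esr = [
            g for g in genome.genes if g not in genome.esr_up and g not in genome.esr_down
        ]
        aps_genes = set(rng.choice(non_esr, size=n_aps_genes, replace=False))
        aps_coefficient = aps_min_shift / min(sizes[c] for c in dup_chroms)

    prone = complex_attenuation_roles(genome, attenuated_complex_fraction, seed)
    truths: dict[str, DisomeTruth] = {}
    protein_cols, mrna_cols = [], []
    for j, chrom in enumerate(dup_chroms):
        strain = f"disome{int(chrom[3:]):02d}"
        truth = default_disome_truth(
            genome,
            chrom,
            prone=prone,
            mu_full=mu_full,
            mu_att=mu_att,
            noise_sd=noise_sd,
            attenuated_complex_fraction=attenuated_complex_fraction,
            attenuated_noncomplex_fraction=attenuated_noncomplex_fraction,
            aps_genes=aps_genes,
            aps_coefficient=aps_coefficient,
            esr_scale=esr_scale,
            seed=seed,
        )
        truths[strain] = truth
        protein_cols.append(
            generate_disome_matrix(
                genome, truth, "protein", seed=(seed * 1000 + 2 * j), strain=strain,
                condition=condition,
            ).data
        )
        mrna_cols.append(
            generate_disome_matrix(
                genome, truth, "mRNA", seed=(seed * 1000 + 2 * j + 1), strain=strain,
                condition=condition,
            ).data
        )
    protein = QuantMatrix(pd.concat(protein_cols, axis=1), "protein", condition)
    mrna = QuantMatrix(pd.concat(mrna_cols, axis=1), "mRNA", condition)
    return SyntheticStudy(genome, truths, protein, mrna, condition)


def null_study(genome: GenomeModel | None = None, noise_sd: float = 0.2,
               seed: int = 0) -> SyntheticStudy:
    """A 12-disome study with dosage effects but no APS, ESR, or attenuation."""
    study = generate_study(
        genome=genome,
        condition="YEPD",
        noise_sd=noise_sd,
        attenuated_complex_fraction=0.0,
        attenuated_noncomplex_fraction=0.0,
        n_aps_genes=0,
        esr_scale=0.0,
        seed=seed,
    )
    return replace(study, condition="null")
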
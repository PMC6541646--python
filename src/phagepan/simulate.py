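"""Synthetic phage populations, host strains and host-range tables.

The generator plants the statistical structure the downstream analysis
assumes, with known ground truth:

* four phage groups of unequal size (default 20/10/4/4, echoing the
  dominance of the cos and pac groups), each with its own pool of ancestral
  gene families plus a small shared pool;
* 40-63 genes per genome: all of the group's core families (13 by default),
  one receptor-binding protein, and mosaic accessory content sampled without
  replacement from the group pool;
* one RBP per genome = a conserved N-terminal region (identical within a
  group) + a lineage-specific variable region (VR2), lineages nested within
  groups;
* host strains carrying an eps operon (genotype-specific gene subset between
  planted epsA and TMS6 marker genes) and an rgp operon (between radC and a
  bactoprenol glucosyl transferase), with more genotype letters for eps (6)
  than rgp (5) so that strains sharing an EPS genotype can hold different
  RGP genotypes;
* a host range linking each phage to strains whose eps genotype matches its
  RBP lineage, optionally corrupted by noise.

Sequences are uniform random over the 20-letter amino-acid alphabet: the
downstream operators consume only identity and coverage, so compositional
realism is unnecessary, while random 100-400-aa proteins sit far below every
orthology threshold.  All randomness flows from one seed through named
substreams, so adding a genome does not perturb the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields
from typing import NamedTuple

import numpy as np

from .records import GeneRecord, Genome
from .tables import HostRangeTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)

EPS_LEFT_PRODUCT = "epsA"
EPS_RIGHT_PRODUCT = "predicted membrane protein (TMS6)"
RGP_LEFT_PRODUCT = "radC"
RGP_RIGHT_PRODUCT = "bactoprenol glucosyl transferase"
RBP_PRODUCT = "receptor binding protein"

SPACER_LEN = 50

# deterministic codon per amino acid (lexicographically smallest, table 11)
_CODONS = {
    "A": "GCA", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC",
    "G": "GGA", "H": "CAC", "I": "ATA", "K": "AAA", "L": "CTA",
    "M": "ATG", "N": "AAC", "P": "CCA", "Q": "CAA", "R": "AGA",
    "S": "AGC", "T": "ACA", "V": "GTA", "W": "TGG", "Y": "TAC",
}
_STOP = "TAA"


def _rng(seed: int, *tokens) -> np.random.Generator:
    """Named substream: independent generator keyed by (seed, tokens)."""
    digest = hashlib.blake2b(
        "/".join(str(t) for t in tokens).encode(), digest_size=8
    ).digest()
    return np.random.default_rng([int(seed), int.from_bytes(digest, "little")])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return bytes(_AA[rng.integers(0, len(_AA), size=length)]).decode()


def mutate_sequence(seq: str, rate: float, seed) -> str:
    """Substitute each position independently with probability ``rate`` to a
    uniformly random *different* residue; length is preserved.

    ``seed`` may be an integer or a numpy Generator.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        current = chr(arr[i])
        choices = AMINO_ACIDS.replace(current, "")
        arr[i] = ord(choices[rng.integers(0, len(choices))])
    return arr.tobytes().decode()


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the generator (defaults = the emulated study)."""

    n_groups: int = 4
    genomes_per_group: tuple[int, ...] = (20, 10, 4, 4)
    genes_per_genome: tuple[int, int] = (40, 63)
    group_pool_size: int = 120  # includes the core families
    shared_pool_size: int = 20
    core_genes_per_group: int = 13
    n_rbp_lineages: int = 7
    n_eps_genotypes: int = 6
    n_rgp_genotypes: int = 5
    n_strains: int = 23
    eps_genes_range: tuple[int, int] = (13, 22)
    rgp_genes_range: tuple[int, int] = (14, 20)
    eps_pool_size: int = 40
    rgp_pool_size: int = 40
    protein_length_range: tuple[int, int] = (100, 400)
    rbp_nterm_len: int = 150
    rbp_vr2_len: int = 250
    rbp_vr2_divergence: float = 0.4
    within_lineage_divergence: float = 0.05
    host_range_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_groups, self.group_pool_size, self.shared_pool_size,
            self.core_genes_per_group, self.n_rbp_lineages,
            self.n_eps_genotypes, self.n_rgp_genotypes, self.n_strains,
            self.eps_pool_size, self.rgp_pool_size,
        ]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if len(self.genomes_per_group) != self.n_groups:
            raise ValueError("genomes_per_group must have n_groups entries")
        for prob in (
            self.rbp_vr2_divergence,
            self.within_lineage_divergence,
            self.host_range_noise,
        ):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.genes_per_genome
        if self.core_genes_per_group + 1 > lo:
            raise ValueError("core genes + RBP exceed the minimum gene count")
        accessory_pool = (self.group_pool_size - self.core_genes_per_group
                          + self.shared_pool_size)
        if accessory_pool < hi - self.core_genes_per_group - 1:
            raise ValueError("gene pool smaller than the maximum genes per genome")
        if self.group_pool_size <= self.core_genes_per_group:
            raise ValueError("group pool must exceed the core gene count")
        if self.eps_genes_range[1] > self.eps_pool_size:
            raise ValueError("eps_genes_range exceeds eps_pool_size")
        if self.rgp_genes_range[1] > self.rgp_pool_size:
            raise ValueError("rgp_genes_range exceeds rgp_pool_size")
        if self.n_rbp_lineages < self.n_groups:
            raise ValueError("need at least one RBP lineage per group")

    # -- flat key=value round-trip (CLI --config) -------------------------

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                value = getattr(self, f.name)
                if isinstance(value, tuple):
                    value = ":".join(str(v) for v in value)
                fh.write(f"{f.name}={value}\n")

    @classmethod
    def from_file(cls, path, **overrides) -> "SimConfig":
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, raw = line.partition("=")
                kwargs[key.strip()] = raw.strip()
        return cls.from_mapping({**kwargs, **overrides})

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        types = {f.name: f.type for f in fields(cls)}
        kwargs: dict = {}
        for key, raw in mapping.items():
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if not isinstance(raw, str):
                kwargs[key] = raw
            elif "tuple" in str(types[key]):
                kwargs[key] = tuple(int(v) for v in raw.split(":"))
            elif "float" in str(types[key]):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(raw)
        return cls(**kwargs)


@dataclass
class SimTruth:
    """Planted labels: the ground truth downstream recovery is scored against."""

    genome_group: dict[str, int] = field(default_factory=dict)
    rbp_lineage: dict[str, int] = field(default_factory=dict)
    strain_eps_genotype: dict[str, int] = field(default_factory=dict)
    strain_rgp_genotype: dict[str, int] = field(default_factory=dict)
    matched_pairs: set[tuple[int, int]] = field(default_factory=set)
    lineage_group: dict[int, int] = field(default_factory=dict)
    gene_family: dict[str, str] = field(default_factory=dict)


class SimulatedPopulation(NamedTuple):
    genomes: list[Genome]
    strains: list[Genome]
    host_range: HostRangeTable
    truth: SimTruth


def _allocate_lineages(n_lineages: int, sizes: tuple[int, ...]) -> list[int]:
    """Lineages per group: one each, remainder by greatest-divisor rounds."""
    counts = [1] * len(sizes)
    for _ in range(n_lineages - len(sizes)):
        ratios = [sizes[g] / counts[g] for g in range(len(sizes))]
        counts[ratios.index(max(ratios))] += 1
    return counts


def _pool(seed: int, name: str, size: int, length_range: tuple[int, int]) -> list[str]:
    out = []
    for i in range(size):
        rng = _rng(seed, "pool", name, i)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(random_protein(rng, length))
    return out


# marker ancestors are fixed literal sequences (independent of the config
# seed) so the annotation-based operon search always finds the same genes
_MARKER_RNG_SEED = 715517
_marker_rng = np.random.default_rng(_MARKER_RNG_SEED)
MARKER_PROTEINS = {
    EPS_LEFT_PRODUCT: random_protein(_marker_rng, 220),
    EPS_RIGHT_PRODUCT: random_protein(_marker_rng, 180),
    RGP_LEFT_PRODUCT: random_protein(_marker_rng, 210),
    RGP_RIGHT_PRODUCT: random_protein(_marker_rng, 190),
}


def _reverse_translate(aa: str) -> str:
    return "".join(_CODONS[c] for c in aa) + _STOP


def _assemble(genome_id: str, entries: list[tuple[str, str, str]], seed: int) -> Genome:
    """Lay (gene_id, product, protein) end to end on one contig with spacers."""
    contig = f"{genome_id}_c1"
    rng = _rng(seed, "spacer", genome_id)
    nt_parts: list[str] = []
    genes: list[GeneRecord] = []
    pos = 0
    nt_alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for gene_id, product, aa in entries:
        spacer = bytes(nt_alphabet[rng.integers(0, 4, size=SPACER_LEN)]).decode()
        nt_parts.append(spacer)
        pos += SPACER_LEN
        cds = _reverse_translate(aa)
        genes.append(
            GeneRecord(
                genome_id=genome_id,
                gene_id=gene_id,
                contig=contig,
                start=pos,
                end=pos + len(cds),
                strand="+",
                product=product,
                protein=aa,
            )
        )
        nt_parts.append(cds)
        pos += len(cds)
    nt_parts.append(bytes(nt_alphabet[rng.integers(0, 4, size=SPACER_LEN)]).decode())
    return Genome(genome_id=genome_id, genes=genes, contigs={contig: "".join(nt_parts)})


def _distinct_subsets(
    seed: int, name: str, n_sets: int, pool: int, size_range: tuple[int, int]
) -> list[list[int]]:
    """n_sets pairwise-distinct sorted index subsets of range(pool)."""
    seen: set[frozenset[int]] = set()
    out: list[list[int]] = []
    for g in range(n_sets):
        for attempt in range(100):
            rng = _rng(seed, name, g, attempt)
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            subset = frozenset(int(x) for x in rng.choice(pool, size=size, replace=False))
            if subset not in seen:
                seen.add(subset)
                out.append(sorted(subset))
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw distinct genotype gene sets")
    return out


def simulate_population(config: SimConfig | None = None) -> SimulatedPopulation:
    """Generate phages, host strains, host range and ground truth.

    Fully deterministic given ``config.seed``.
    """
    config = config or SimConfig()
    seed = config.seed
    lo, hi = config.genes_per_genome
    div = config.within_lineage_divergence

    # ancestral gene family pools
    group_pools = [
        _pool(seed, f"group{g}", config.group_pool_size, config.protein_length_range)
        for g in range(config.n_groups)
    ]
    shared_pool = _pool(seed, "shared", config.shared_pool_size, config.protein_length_range)

    # RBP components: conserved N-terminal per group, VR2 per lineage
    lineage_counts = _allocate_lineages(config.n_rbp_lineages, config.genomes_per_group)
    lineages_of_group: list[list[int]] = []
    lineage_group: dict[int, int] = {}
    nxt = 0
    for g, cnt in enumerate(lineage_counts):
        ids = list(range(nxt, nxt + cnt))
        lineages_of_group.append(ids)
        for lin in ids:
            lineage_group[lin] = g
        nxt += cnt
    nterm = [
        random_protein(_rng(seed, "rbp_nterm", g), config.rbp_nterm_len)
        for g in range(config.n_groups)
    ]
    vr2_ancestor = [
        random_protein(_rng(seed, "vr2_ancestor", g), config.rbp_vr2_len)
        for g in range(config.n_groups)
    ]
    vr2 = {
        lin: mutate_sequence(
            vr2_ancestor[lineage_group[lin]],
            config.rbp_vr2_divergence,
            _rng(seed, "vr2", lin),
        )
        for lin in lineage_group
    }

    truth = SimTruth(lineage_group=dict(lineage_group))
    genomes: list[Genome] = []
    for g in range(config.n_groups):
        pool = group_pools[g]
        core = list(range(config.core_genes_per_group))
        accessory_families = [
            (f"g{g}F{k}", pool[k])
            for k in range(config.core_genes_per_group, config.group_pool_size)
        ] + [(f"SF{k}", shared_pool[k]) for k in range(config.shared_pool_size)]
        for idx in range(config.genomes_per_group[g]):
            genome_id = f"PHAGE_g{g + 1}_{idx + 1:02d}"
            rng = _rng(seed, "genome", genome_id)
            n_genes = int(rng.integers(lo, hi + 1))
            n_accessory = n_genes - config.core_genes_per_group - 1
            chosen = rng.choice(len(accessory_families), size=n_accessory, replace=False)
            lineage = lineages_of_group[g][idx % len(lineages_of_group[g])]
            entries: list[tuple[str, str, str]] = [
                (f"g{g}C{k}", "structural protein", pool[k]) for k in core
            ]
            entries += [
                (fam_id, "hypothetical protein", ancestor)
                for fam_id, ancestor in (accessory_families[int(c)] for c in sorted(chosen))
            ]
            entries.append(("RBP", RBP_PRODUCT, None))  # placeholder, handled below
            order = rng.permutation(len(entries))
            laid: list[tuple[str, str, str]] = []
            for pos, entry_idx in enumerate(order):
                fam_id, product, ancestor = entries[int(entry_idx)]
                gene_id = f"{genome_id}_g{pos + 1:03d}"
                if product == RBP_PRODUCT:
                    protein = nterm[g] + mutate_sequence(
                        vr2[lineage], div, _rng(seed, "mut", genome_id, "RBP")
                    )
                    truth.gene_family[gene_id] = f"RBP_g{g}"
                else:
                    protein = mutate_sequence(
                        ancestor, div, _rng(seed, "mut", genome_id, fam_id)
                    )
                    truth.gene_family[gene_id] = fam_id
                laid.append((gene_id, product, protein))
            genomes.append(_assemble(genome_id, laid, seed))
            truth.genome_group[genome_id] = g
            truth.rbp_lineage[genome_id] = lineage

    # strains: eps and rgp operons with genotype-specific gene content
    eps_pool = _pool(seed, "eps", config.eps_pool_size, (100, 300))
    rgp_pool = _pool(seed, "rgp", config.rgp_pool_size, (100, 300))
    eps_sets = _distinct_subsets(
        seed, "eps_sets", config.n_eps_genotypes, config.eps_pool_size, config.eps_genes_range
    )
    rgp_sets = _distinct_subsets(
        seed, "rgp_sets", config.n_rgp_genotypes, config.rgp_pool_size, config.rgp_genes_range
    )
    strains: list[Genome] = []
    for j in range(config.n_strains):
        strain_id = f"STRAIN_{j + 1:02d}"
        eps_geno = j % config.n_eps_genotypes
        rgp_geno = j % config.n_rgp_genotypes
        entries = []
        counter = 0

        def filler() -> tuple[str, str, str]:
            nonlocal counter
            counter += 1
            rng = _rng(seed, "filler", strain_id, counter)
            return (
                f"{strain_id}_f{counter}",
                "hypothetical protein",
                random_protein(rng, int(rng.integers(100, 301))),
            )

        def marked(product: str) -> tuple[str, str, str]:
            return (
                f"{strain_id}_{product.split()[0]}",
                product,
                mutate_sequence(
                    MARKER_PROTEINS[product], div, _rng(seed, "mut", strain_id, product)
                ),
            )

        entries += [filler() for _ in range(3)]
        entries.append(marked(EPS_LEFT_PRODUCT))
        for k in eps_sets[eps_geno]:
            entries.append(
                (
                    f"{strain_id}_eps{k}",
                    "eps cluster protein",
                    mutate_sequence(eps_pool[k], div, _rng(seed, "mut", strain_id, f"EF{k}")),
                )
            )
        entries.append(marked(EPS_RIGHT_PRODUCT))
        entries += [filler() for _ in range(2)]
        entries.append(marked(RGP_LEFT_PRODUCT))
        for k in rgp_sets[rgp_geno]:
            entries.append(
                (
                    f"{strain_id}_rgp{k}",
                    "rgp cluster protein",
                    mutate_sequence(rgp_pool[k], div, _rng(seed, "mut", strain_id, f"RF{k}")),
                )
            )
        entries.append(marked(RGP_RIGHT_PRODUCT))
        entries += [filler() for _ in range(2)]
        strains.append(_assemble(strain_id, entries, seed))
        truth.strain_eps_genotype[strain_id] = eps_geno
        truth.strain_rgp_genotype[strain_id] = rgp_geno

    truth.matched_pairs = {
        (lin, lin % config.n_eps_genotypes) for lin in lineage_group
    }
    matched_of = dict(truth.matched_pairs)

    # host range: phages infect strains of the matched eps genotype
    strain_ids = [s.genome_id for s in strains]
    by_genotype: dict[int, list[str]] = {}
    for sid in strain_ids:
        by_genotype.setdefault(truth.strain_eps_genotype[sid], []).append(sid)
    entries_hr: dict[str, set[str]] = {}
    for genome in genomes:
        rng = _rng(seed, "host", genome.genome_id)
        genotype = matched_of[truth.rbp_lineage[genome.genome_id]]
        matching = by_genotype.get(genotype, [])
        others = [s for s in strain_ids if s not in matching]
        n_hosts = 1 + int(rng.random() < 0.15)
        n_hosts = min(n_hosts, len(matching)) or 1
        picked = [matching[int(i)] for i in rng.choice(len(matching), size=n_hosts, replace=False)]
        hosts: set[str] = set()
        for strain in picked:
            if others and rng.random() < config.host_range_noise:
                hosts.add(others[int(rng.integers(0, len(others)))])
            else:
                hosts.add(strain)
        entries_hr[genome.genome_id] = hosts
    host_range = HostRangeTable(entries_hr)
    return SimulatedPopulation(genomes, strains, host_range, truth)


def proteomes_of(genomes: list[Genome]) -> dict[str, dict[str, str]]:
    return {g.genome_id: g.proteome() for g in genomes}


def write_population(pop: SimulatedPopulation, config: SimConfig, outdir) -> None:
    """Write FASTA/GFF3 per genome plus host_range.tsv, truth.tsv, config.used."""
    from pathlib import Path

    from .genomeio import write_genome

    out = Path(outdir)
    (out / "phages").mkdir(parents=True, exist_ok=True)
    (out / "strains").mkdir(parents=True, exist_ok=True)
    for genome in pop.genomes:
        write_genome(genome, out / "phages" / f"{genome.genome_id}.fna",
                     out / "phages" / f"{genome.genome_id}.gff3")
    for strain in pop.strains:
        write_genome(strain, out / "strains" / f"{strain.genome_id}.fna",
                     out / "strains" / f"{strain.genome_id}.gff3")
    pop.host_range.to_tsv(out / "host_range.tsv")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("entity\tkind\tvalue\n")
        for gid, grp in sorted(pop.truth.genome_group.items()):
            fh.write(f"{gid}\tgroup\t{grp}\n")
        for gid, lin in sorted(pop.truth.rbp_lineage.items()):
            fh.write(f"{gid}\trbp_lineage\t{lin}\n")
        for sid, g in sorted(pop.truth.strain_eps_genotype.items()):
            fh.write(f"{sid}\teps_genotype\t{g}\n")
        for sid, g in sorted(pop.truth.strain_rgp_genotype.items()):
            fh.write(f"{sid}\trgp_genotype\t{g}\n")
    config.to_file(out / "config.used")
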
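"""Synthetic proteomes, gene layouts and count matrices with planted truth.

Every generator is deterministic given its spec and seed, and returns both
the standard-format artifact (FASTA / GFF3 / TSV text) and a truth table
sufficient to verify downstream recovery without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import census
from .census import AMINO_ACIDS, CANONICAL_TOKENS, DomainModel

_AA = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)

#: Default consensus lengths per token for :func:`default_domain_models`.
_MODEL_LENGTHS = {"SP": 15, "LRR": 24, "MD": 60, "TMD": 21, "PK": 50, "Kin": 45, "CC": 28}


def default_domain_models(min_identity: float = 0.75, seed: int = 715) -> list[DomainModel]:
    """Fixed random consensus models, one per scanner token."""
    rng = np.random.default_rng(seed)
    models = []
    for name in sorted(_MODEL_LENGTHS):
        consensus = "".join(rng.choice(list(AMINO_ACIDS), size=_MODEL_LENGTHS[name]))
        models.append(DomainModel(name, consensus, min_identity))
    return models


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Substitute each residue with probability *rate* by a different residue."""
    if rate <= 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(arr.size) < rate
    for i in np.flatnonzero(mask):
        choices = _AA[_AA != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _mutate_exact(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Mutate exactly round(rate * len) distinct positions.

    Used for clade-private consensi so short models cannot drift below their
    detection threshold by sampling noise.
    """
    n_mut = int(round(rate * len(sequence)))
    if n_mut == 0:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    for i in rng.choice(arr.size, size=n_mut, replace=False):
        choices = _AA[_AA != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _wrap_fasta(pid: str, seq: str, width: int = 60) -> str:
    lines = [f">{pid}"]
    lines += [seq[i : i + width] for i in range(0, len(seq), width)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Proteome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamilySpec:
    """Planted family: one architecture and gene count per clade.

    Architectures may use the MLD token; the generator expands it into two MD
    consensus copies separated by a short spacer (well under the default
    collapse gap), so the censused architecture matches the planted one.

    clade_divergence mutates each clade's private copy of the consensus
    models once, before per-gene substitution, making clades separable by
    phylogenetic distance even when architectures coincide.
    """

    architectures: tuple[tuple[str, ...], ...]
    genes_per_clade: tuple[int, ...]
    substitution_rate: float = 0.02
    background_genes: int = 0
    clade_divergence: float = 0.0
    linker_length: tuple[int, int] = (10, 40)
    mld_spacing: tuple[int, int] = (10, 40)
    background_length: tuple[int, int] = (200, 600)

    def __post_init__(self) -> None:
        if len(self.architectures) != len(self.genes_per_clade):
            raise ValueError("architectures and genes_per_clade lengths differ")
        for arch in self.architectures:
            for token in arch:
                if token not in CANONICAL_TOKENS:
                    raise ValueError(f"unknown architecture token {token!r}")
        if any(n < 1 for n in self.genes_per_clade):
            raise ValueError("genes per clade must be positive")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.background_genes < 0:
            raise ValueError("background_genes must be non-negative")

    @property
    def n_family(self) -> int:
        return int(sum(self.genes_per_clade))


@dataclass(frozen=True)
class SimulatedProteome:
    fasta: str
    proteins: pd.DataFrame  # protein, clade, architecture, length
    hits: pd.DataFrame  # protein, token, start, end (planted truth)
    sequences: Mapping[str, str]


def generate_proteome(
    spec: FamilySpec, models: Sequence[DomainModel], seed: int
) -> SimulatedProteome:
    """Assemble family proteins from mutated consensus copies plus linkers.

    Background proteins are rejection-sampled so they contain no window at or
    above any model's identity threshold.
    """
    rng = np.random.default_rng(seed)
    by_name = {m.name: m for m in models}
    detectability = spec.clade_divergence + spec.substitution_rate
    for arch in spec.architectures:
        for token in arch:
            lookup = "MD" if token == "MLD" else token
            if lookup not in by_name:
                raise ValueError(f"no model for architecture token {token!r}")
            if 1.0 - detectability < by_name[lookup].min_identity:
                raise ValueError(
                    "substitution_rate + clade_divergence leaves no detectability "
                    f"margin for model {lookup!r} (min_identity "
                    f"{by_name[lookup].min_identity})"
                )

    # per-clade private consensi
    clade_consensi: list[dict[str, str]] = []
    for _ in spec.architectures:
        clade_consensi.append(
            {
                name: _mutate_exact(rng, model.consensus, spec.clade_divergence)
                for name, model in by_name.items()
            }
        )

    lo, hi = spec.linker_length
    fasta_parts: list[str] = []
    protein_rows, hit_rows = [], []
    sequences: dict[str, str] = {}
    counter = 0
    for clade_idx, (arch, n_genes) in enumerate(
        zip(spec.architectures, spec.genes_per_clade)
    ):
        clade_id = f"C{clade_idx + 1}"
        # expand MLD into planted MD pairs
        planted: list[str] = []
        for token in arch:
            planted += ["MD", "MD"] if token == "MLD" else [token]
        for _ in range(n_genes):
            counter += 1
            pid = f"FAM{counter:04d}"
            parts = [_random_peptide(rng, int(rng.integers(5, 26)))]
            pos = len(parts[0])
            gene_hits = []
            prev_token = None
            for k, token in enumerate(planted):
                if k > 0:
                    if prev_token == "MD" and token == "MD" and planted[k - 1] == "MD" and _is_mld_pair(arch, k, planted):
                        spacer_len = int(rng.integers(*spec.mld_spacing))
                    elif prev_token == "MD" and token == "MD":
                        # standalone MD followed by another MD: keep them apart
                        spacer_len = census.DEFAULT_MLD_GAP + int(rng.integers(10, 60))
                    else:
                        spacer_len = int(rng.integers(lo, hi + 1))
                    parts.append(_random_peptide(rng, spacer_len))
                    pos += spacer_len
                domain = _mutate(
                    rng, clade_consensi[clade_idx][token], spec.substitution_rate
                )
                parts.append(domain)
                gene_hits.append((token, pos + 1, pos + len(domain)))
                pos += len(domain)
                prev_token = token
            parts.append(_random_peptide(rng, int(rng.integers(5, 26))))
            seq = "".join(parts)
            fasta_parts.append(_wrap_fasta(pid, seq))
            sequences[pid] = seq
            protein_rows.append(
                {
                    "protein": pid,
                    "clade": clade_id,
                    "architecture": "-".join(arch),
                    "length": len(seq),
                }
            )
            for token, start, end in gene_hits:
                hit_rows.append(
                    {"protein": pid, "token": token, "start": start, "end": end}
                )

    blo, bhi = spec.background_length
    for b in range(spec.background_genes):
        pid = f"BG{b + 1:04d}"
        for _ in range(100):
            seq = _random_peptide(rng, int(rng.integers(blo, bhi + 1)))
            if not census.scan_domains(pid, seq, models):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not sample a clean background protein")
        fasta_parts.append(_wrap_fasta(pid, seq))
        sequences[pid] = seq
        protein_rows.append(
            {"protein": pid, "clade": "", "architecture": "", "length": len(seq)}
        )

    return SimulatedProteome(
        fasta="".join(fasta_parts),
        proteins=pd.DataFrame(
            protein_rows, columns=["protein", "clade", "architecture", "length"]
        ),
        hits=pd.DataFrame(hit_rows, columns=["protein", "token", "start", "end"]),
        sequences=sequences,
    )


def _is_mld_pair(arch: Sequence[str], k: int, planted: Sequence[str]) -> bool:
    """Is planted[k] the second half of an expanded MLD token?

    Walk the architecture expansion in parallel to find out.
    """
    i = 0
    for token in arch:
        if token == "MLD":
            if i + 1 == k:
                return True
            i += 2
        else:
            i += 1
    return False


# ---------------------------------------------------------------------------
# Gene layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedCluster:
    seqid: str
    n_members: int
    max_intervening: int
    max_gap: int

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("planted cluster must have >= 2 members")
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be non-negative")


@dataclass(frozen=True)
class LayoutSpec:
    chromosomes: tuple[tuple[str, int], ...]  # (name, length bp)
    planted_clusters: tuple[PlantedCluster, ...] = ()
    scaffold_fraction: float = 0.0
    gene_length: tuple[int, int] = (1500, 4500)
    family_exons: tuple[int, int] = (1, 12)
    background_exons: tuple[int, int] = (1, 8)

    def __post_init__(self) -> None:
        names = {n for n, _ in self.chromosomes}
        for pc in self.planted_clusters:
            if pc.seqid not in names:
                raise ValueError(f"planted cluster on unknown chromosome {pc.seqid!r}")
        if not 0.0 <= self.scaffold_fraction <= 1.0:
            raise ValueError("scaffold_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulatedGenome:
    gff: str
    genes: pd.DataFrame  # gene, seqid, start, end, strand, n_exons, is_family
    clusters: tuple[tuple[str, tuple[str, ...]], ...]  # (seqid, member ids)


_BG_GENE_LEN = 1000


def generate_gene_models(
    family_ids: Sequence[str], layout: LayoutSpec, seed: int
) -> SimulatedGenome:
    """Place family genes on chromosomes/scaffolds with planted tandem clusters.

    Cluster members satisfy their planted intervening-gene and start-to-start
    gap bounds; every other family gene is isolated from any family neighbor
    by more than the largest planted (or default) bound on both counts.
    """
    rng = np.random.default_rng(seed)
    family_ids = list(family_ids)
    n_family = len(family_ids)
    needed = sum(pc.n_members for pc in layout.planted_clusters)
    if needed > n_family:
        raise ValueError("planted clusters demand more members than family genes")

    n_scaffold = int(round(layout.scaffold_fraction * n_family))
    if needed + n_scaffold > n_family:
        raise ValueError("scaffold_fraction leaves too few genes for planted clusters")

    pool = list(family_ids)
    cluster_members: list[tuple[PlantedCluster, list[str]]] = []
    for pc in layout.planted_clusters:
        cluster_members.append((pc, [pool.pop(0) for _ in range(pc.n_members)]))
    scaffold_genes = [pool.pop() for _ in range(n_scaffold)]
    isolated = pool

    # separation bounds guaranteeing isolation under any planted rule
    max_int = max([pc.max_intervening for pc in layout.planted_clusters] + [8])
    max_gap = max([pc.max_gap for pc in layout.planted_clusters] + [250_000])
    sep_n_bg = max_int + 2
    sep_gap = int(max_gap * 1.5)

    chrom_names = [n for n, _ in layout.chromosomes]
    chrom_len = dict(layout.chromosomes)
    # entities per chromosome: clusters pinned, isolated genes round-robin
    entities: dict[str, list] = {n: [] for n in chrom_names}
    for pc, members in cluster_members:
        entities[pc.seqid].append(("cluster", pc, members))
    for i, gid in enumerate(isolated):
        entities[chrom_names[i % len(chrom_names)]].append(("single", None, [gid]))

    glo, ghi = layout.gene_length
    rows: list[dict] = []
    clusters_truth: list[tuple[str, tuple[str, ...]]] = []
    bg_counter = 0

    def emit(seqid: str, gid: str, start: int, length: int, is_family: bool) -> int:
        nonlocal bg_counter
        end = start + length - 1
        if end > chrom_len.get(seqid, end):
            raise ValueError(f"chromosome {seqid} overflow at {end} bp")
        elo, ehi = layout.family_exons if is_family else layout.background_exons
        n_exons = int(rng.integers(elo, ehi + 1))
        rows.append(
            {
                "gene": gid,
                "seqid": seqid,
                "start": start,
                "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "n_exons": n_exons,
                "is_family": is_family,
            }
        )
        return end

    def emit_bg(seqid: str, start: int) -> int:
        nonlocal bg_counter
        bg_counter += 1
        return emit(seqid, f"NF{bg_counter:05d}", start, _BG_GENE_LEN, False)

    for seqid in chrom_names:
        cursor = 1000
        for kind, pc, members in entities[seqid]:
            # leading separation block: sep_n_bg background genes over > sep_gap
            spacing = max(sep_gap // (sep_n_bg + 1) + 1, _BG_GENE_LEN + 200)
            for _ in range(sep_n_bg):
                end = emit_bg(seqid, cursor)
                cursor = end + spacing
            cursor += spacing  # extra margin so family-to-family gap > sep_gap
            if kind == "single":
                length = int(rng.integers(glo, ghi + 1))
                end = emit(seqid, members[0], cursor, length, True)
                cursor = end + 1
            else:
                for j, gid in enumerate(members):
                    length = int(rng.integers(glo, ghi + 1))
                    start = cursor
                    end = emit(seqid, gid, start, length, True)
                    if j == len(members) - 1:
                        cursor = end + 1
                        break
                    n_int = int(rng.integers(0, pc.max_intervening + 1))
                    # fit n_int background genes within the gap budget
                    while n_int > 0 and length + n_int * (_BG_GENE_LEN + 100) + 100 > pc.max_gap:
                        n_int -= 1
                    budget = pc.max_gap - length - n_int * _BG_GENE_LEN
                    if budget < (n_int + 1) * 50:
                        raise ValueError(
                            f"max_gap {pc.max_gap} too small for planted cluster "
                            f"on {seqid}"
                        )
                    s = min(600, budget // (n_int + 1) - 10)
                    pos = end + s
                    for _ in range(n_int):
                        bend = emit_bg(seqid, pos)
                        pos = bend + s
                    gap = pos - start
                    assert gap <= pc.max_gap, "internal: planted gap exceeds bound"
                    cursor = pos
                clusters_truth.append((seqid, tuple(members)))
        # trailing separation
        spacing = max(sep_gap // (sep_n_bg + 1) + 1, _BG_GENE_LEN + 200)
        for _ in range(sep_n_bg):
            end = emit_bg(seqid, cursor)
            cursor = end + spacing

    for i, gid in enumerate(scaffold_genes):
        seqid = f"scaffold_{i + 1}"
        length = int(rng.integers(glo, ghi + 1))
        elo, ehi = layout.family_exons
        rows.append(
            {
                "gene": gid,
                "seqid": seqid,
                "start": 1000,
                "end": 1000 + length - 1,
                "strand": "+" if rng.random() < 0.5 else "-",
                "n_exons": int(rng.integers(elo, ehi + 1)),
                "is_family": True,
            }
        )

    genes = pd.DataFrame(
        rows,
        columns=["gene", "seqid", "start", "end", "strand", "n_exons", "is_family"],
    )
    gff = _write_gff(genes, rng)
    return SimulatedGenome(gff=gff, genes=genes, clusters=tuple(clusters_truth))


def _exon_spans(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> list[tuple[int, int]]:
    """Partition [start, end] into n_exons exons alternating with introns."""
    total = end - start + 1
    if n_exons == 1:
        return [(start, end)]
    n_cuts = 2 * n_exons - 2
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_cuts, replace=False))
    bounds = np.concatenate(([0], cuts, [total]))
    spans = []
    for k in range(0, len(bounds) - 1, 2):
        spans.append((start + int(bounds[k]), start + int(bounds[k + 1]) - 1))
    return spans


def _write_gff(genes: pd.DataFrame, rng: np.random.Generator) -> str:
    lines = ["##gff-version 3"]
    for row in genes.itertuples():
        attrs = f"ID={row.gene}"
        lines.append(
            "\t".join(
                [
                    row.seqid,
                    "genefam_sim",
                    "gene",
                    str(row.start),
                    str(row.end),
                    ".",
                    row.strand,
                    ".",
                    attrs,
                ]
            )
        )
        mrna = f"{row.gene}.1"
        lines.append(
            "\t".join(
                [
                    row.seqid,
                    "genefam_sim",
                    "mRNA",
                    str(row.start),
                    str(row.end),
                    ".",
                    row.strand,
                    ".",
                    f"ID={mrna};Parent={row.gene}",
                ]
            )
        )
        for k, (es, ee) in enumerate(
            _exon_spans(rng, row.start, row.end, row.n_exons), start=1
        ):
            lines.append(
                "\t".join(
                    [
                        row.seqid,
                        "genefam_sim",
                        "exon",
                        str(es),
                        str(ee),
                        ".",
                        row.strand,
                        ".",
                        f"ID={mrna}.exon{k};Parent={mrna}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedModule:
    """Genes sharing a latent per-sample multiplier; sign -1 anti-correlates."""

    name: str
    genes: tuple[str, ...]
    signs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.signs and len(self.signs) != len(self.genes):
            raise ValueError("signs must match genes in length")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be +1 or -1")

    def sign_of(self, gene: str) -> int:
        if not self.signs:
            return 1
        return self.signs[self.genes.index(gene)]


@dataclass(frozen=True)
class ExpressionSpec:
    tissues: tuple[str, ...]
    experiments: tuple[tuple[str, float], ...]  # (label, library-size factor)
    mean_profile: pd.DataFrame  # genes x tissues, non-negative
    dispersion: float
    replicates: int
    seed: int
    modules: tuple[PlantedModule, ...] = ()
    latent_sd: float = 0.6
    size_factor_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per tissue are required")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if (self.mean_profile.values < 0).any():
            raise ValueError("mean profile must be non-negative")
        if list(self.mean_profile.columns) != list(self.tissues):
            raise ValueError("mean_profile columns must equal tissues")
        seen: set[str] = set()
        for mod in self.modules:
            if seen & set(mod.genes):
                raise ValueError("planted modules must be disjoint")
            seen |= set(mod.genes)
            missing = set(mod.genes) - set(self.mean_profile.index)
            if missing:
                raise ValueError(f"module genes absent from profile: {sorted(missing)}")


@dataclass(frozen=True)
class SimulatedCounts:
    counts: Mapping[str, pd.DataFrame]  # per experiment, genes x samples
    metadata: pd.DataFrame  # sample, tissue, experiment
    peak_tissue: pd.Series  # planted truth, per gene
    modules: tuple[PlantedModule, ...]
    latents: Mapping[str, np.ndarray]  # module name -> latent per sample (all exps)


def generate_counts(spec: ExpressionSpec) -> SimulatedCounts:
    """Negative-binomial counts around size-factor-scaled tissue means.

    Variance model: mu + mu^2 * dispersion.  Genes of a planted module share
    a per-sample latent log-multiplier with the stated sign.
    """
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.mean_profile.index)
    meta_rows = []
    samples_per_exp: dict[str, list[str]] = {}
    tissue_of: dict[str, str] = {}
    for exp, _ in spec.experiments:
        samples_per_exp[exp] = []
        for tissue in spec.tissues:
            for r in range(1, spec.replicates + 1):
                sid = f"{exp}.{tissue}.r{r}"
                samples_per_exp[exp].append(sid)
                tissue_of[sid] = tissue
                meta_rows.append({"sample": sid, "tissue": tissue, "experiment": exp})

    all_samples = [s for exp, _ in spec.experiments for s in samples_per_exp[exp]]
    latents = {
        mod.name: rng.normal(0.0, 1.0, size=len(all_samples)) for mod in spec.modules
    }
    sample_pos = {s: i for i, s in enumerate(all_samples)}

    gene_module: dict[str, tuple[str, int]] = {}
    for mod in spec.modules:
        for g in mod.genes:
            gene_module[g] = (mod.name, mod.sign_of(g))

    inv_disp = 1.0 / spec.dispersion
    counts: dict[str, pd.DataFrame] = {}
    for exp, lib_factor in spec.experiments:
        cols = {}
        for sid in samples_per_exp[exp]:
            sf = lib_factor * float(
                rng.lognormal(0.0, spec.size_factor_jitter)
            )
            mu = spec.mean_profile[tissue_of[sid]].to_numpy(dtype=float).copy()
            mult = np.ones(len(genes))
            for gi, g in enumerate(genes):
                if g in gene_module:
                    name, sign = gene_module[g]
                    mult[gi] = np.exp(
                        spec.latent_sd * sign * latents[name][sample_pos[sid]]
                    )
            mu = mu * sf * mult
            col = np.zeros(len(genes), dtype=np.int64)
            pos = mu > 0
            p = inv_disp / (inv_disp + mu[pos])
            col[pos] = rng.negative_binomial(inv_disp, p)
            cols[sid] = col
        counts[exp] = pd.DataFrame(cols, index=genes)

    profile = spec.mean_profile.to_numpy(dtype=float)
    peak = pd.Series(
        [spec.tissues[int(np.argmax(profile[i]))] for i in range(len(genes))],
        index=genes,
        name="peak_tissue",
    )
    return SimulatedCounts(
        counts=counts,
        metadata=pd.DataFrame(meta_rows, columns=["sample", "tissue", "experiment"]),
        peak_tissue=peak,
        modules=spec.modules,
        latents=latents,
    )
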
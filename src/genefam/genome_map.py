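"""Gene models on chromosomes/scaffolds: GFF3 IO, tandem clusters, introns."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seqid: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end {self.end} < start {self.start}")
        prev_end = None
        for es, ee in self.exons:
            if ee < es:
                raise ValueError(f"gene {self.gene_id}: exon end {ee} < start {es}")
            if es < self.start or ee > self.end:
                raise ValueError(f"gene {self.gene_id}: exon {es}..{ee} outside gene span")
            if prev_end is not None and es <= prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ee


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    seqid: str
    members: tuple[str, ...]
    span: int


@dataclass(frozen=True)
class ClusterRule:
    """Chain rule: both bounds must hold between consecutive family members.

    Surrogate for the (uncited) tandem-cluster definition: at most
    *max_intervening* non-family gene models and at most *max_gap* bp
    (start-to-start) between consecutive members.
    """

    max_intervening: int = 8
    max_gap: int = 250_000


def _parse_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff(source) -> list[GeneModel]:
    """Parse gene models with exon children from GFF3 text or a file path.

    Coordinates stay 1-based inclusive.  Unknown feature types are ignored;
    exons are attached through mRNA parents or directly to genes.  Exons
    outside their parent's span and reversed coordinates are errors.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.startswith("##"):
            with open(text) as fh:
                text = fh.read()

    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        seqid, _, ftype, start_s, end_s, _, strand, _, attr = fields
        start, end = int(start_s), int(end_s)
        attrs = _parse_attributes(attr)
        fid = attrs.get("ID", "")
        if ftype == "gene":
            if end < start:
                raise ValueError(f"feature {fid}: end {end} < start {start}")
            genes[fid] = {"seqid": seqid, "start": start, "end": end, "strand": strand}
            order.append(fid)
        elif ftype == "mRNA":
            mrna_parent[fid] = attrs.get("Parent", "")
        elif ftype == "exon":
            if end < start:
                raise ValueError(f"feature {fid or attr}: end {end} < start {start}")
            parent = attrs.get("Parent", "")
            gene_id = mrna_parent.get(parent, parent)
            exons.setdefault(gene_id, []).append((start, end))

    models = []
    for gid in order:
        info = genes[gid]
        spans = tuple(sorted(exons.get(gid, [])))
        for es, ee in spans:
            if es < info["start"] or ee > info["end"]:
                raise ValueError(f"exon {es}..{ee} outside span of gene {gid}")
        models.append(
            GeneModel(gid, info["seqid"], info["start"], info["end"], info["strand"], spans)
        )
    return models


def count_introns(gene: GeneModel) -> int:
    """Introns = exon count - 1; a gene without exons is an error."""
    if not gene.exons:
        raise ValueError(f"gene {gene.gene_id} has no exons")
    return len(gene.exons) - 1


def _cluster_label(seqid: str, index: int) -> str:
    if seqid.startswith("Chr"):
        return f"C{seqid[3:]}.{index}"
    return f"C{seqid}.{index}"


def detect_tandem_clusters(
    family_ids: Iterable[str],
    genes: Sequence[GeneModel],
    rule: ClusterRule = ClusterRule(),
    exclude_scaffolds: bool = False,
    chromosome_prefix: str = "Chr",
) -> list[GeneCluster]:
    """Chain consecutive family genes per seqid while both rule bounds hold.

    Maximal chains of length >= 2 become clusters; ids are assigned per seqid
    in positional order.  Strand is ignored (tandem repeats may be inverted).
    """
    family = set(family_ids)
    known = {g.gene_id for g in genes}
    missing = sorted(family - known)
    if missing:
        raise ValueError(f"family ids absent from gene list: {missing}")

    by_seq: dict[str, list[GeneModel]] = {}
    for g in sorted(genes, key=lambda g: (g.seqid, g.start)):
        if exclude_scaffolds and not g.seqid.startswith(chromosome_prefix):
            continue
        by_seq.setdefault(g.seqid, []).append(g)

    clusters: list[GeneCluster] = []
    for seqid in sorted(by_seq):
        ordered = by_seq[seqid]
        fam_idx = [i for i, g in enumerate(ordered) if g.gene_id in family]
        chains: list[list[int]] = []
        current: list[int] = []
        for prev, cur in zip([None] + fam_idx[:-1], fam_idx):
            if prev is None:
                current = [cur]
                continue
            intervening = cur - prev - 1
            gap = ordered[cur].start - ordered[prev].start
            if intervening <= rule.max_intervening and gap <= rule.max_gap:
                current.append(cur)
            else:
                chains.append(current)
                current = [cur]
        if current:
            chains.append(current)
        counter = 0
        for chain in chains:
            if len(chain) < 2:
                continue
            counter += 1
            members = tuple(ordered[i].gene_id for i in chain)
            span = ordered[chain[-1]].end - ordered[chain[0]].start + 1
            clusters.append(
                GeneCluster(_cluster_label(seqid, counter), seqid, members, span)
            )
    return clusters


def localization_summary(
    genes: Sequence[GeneModel], chromosome_prefix: str = "Chr"
) -> dict:
    """Counts of chromosomal vs scaffold genes and percent chromosomal.

    The percentage is rounded to the nearest integer.
    """
    chromosomal = sum(1 for g in genes if g.seqid.startswith(chromosome_prefix))
    scaffold = len(genes) - chromosomal
    total = len(genes)
    percent = int(round(100.0 * chromosomal / total)) if total else 0
    return {
        "chromosomal": chromosomal,
        "scaffold": scaffold,
        "percent_chromosomal": percent,
    }


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    rows = [
        {
            "cluster": c.cluster_id,
            "seqid": c.seqid,
            "members": ";".join(c.members),
            "span": c.span,
        }
        for c in clusters
    ]
    return pd.DataFrame(rows, columns=["cluster", "seqid", "members", "span"])
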
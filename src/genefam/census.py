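"""Domain census: locate domain instances, build architectures, classify superclades.

The scanner is a deliberately simple exact-position sliding-window matcher
against ungapped consensus models.  It is not a profile-HMM; precomputed hit
tables (e.g. from hmmscan) can be supplied instead wherever a hit list is
accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical architecture tokens.  MLD only ever arises by collapsing a
#: tandem MD pair, so domain *models* use the set without MLD.
CANONICAL_TOKENS = ("SP", "LRR", "MD", "MLD", "TMD", "PK", "Kin", "CC")
MODEL_TOKENS = ("SP", "LRR", "MD", "TMD", "PK", "Kin", "CC")

SUPERCLADES = ("LRR-MD-PK", "MLD-LRR-PK", "MLD-PK", "MLD-LRR", "MD-Kin", "Unclassified")

#: Tokens ignored by the superclade rules.
_NEUTRAL_TOKENS = frozenset({"SP", "TMD", "CC"})

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default gap (residues) under which two consecutive MD hits collapse to MLD.
DEFAULT_MLD_GAP = 120

# Average residue masses (Da); free amino acid = residue + one water.
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_WATER_MASS = 18.0153
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)

# EMBOSS pKa values for the charge model behind the isoelectric point.
_PKA_POSITIVE = {"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5}
_PKA_NEGATIVE = {"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}


@dataclass(frozen=True)
class DomainModel:
    """Ungapped consensus model for one domain token."""

    name: str
    consensus: str
    min_identity: float

    def __post_init__(self) -> None:
        if self.name not in MODEL_TOKENS:
            raise ValueError(
                f"unknown domain token {self.name!r}; expected one of {MODEL_TOKENS}"
            )
        if len(self.consensus) < 10:
            raise ValueError("consensus length must be >= 10")
        if not 0.0 <= self.min_identity <= 1.0:
            raise ValueError("min_identity must be in [0, 1]")


@dataclass(frozen=True, order=True)
class DomainHit:
    """A located domain instance, 1-based inclusive coordinates."""

    protein_id: str
    token: str
    start: int
    end: int
    identity: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad hit coordinates {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_identities(sequence: str, consensus: str) -> np.ndarray:
    """Exact-position identity of *consensus* at every offset of *sequence*.

    Returns an array of length ``len(sequence) - len(consensus) + 1``
    (empty if the protein is shorter than the model).
    """
    m = len(consensus)
    if len(sequence) < m:
        return np.empty(0)
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    cons = np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, m)
    return (windows == cons).mean(axis=1)


def scan_domains(
    protein_id: str, sequence: str, models: Sequence[DomainModel]
) -> list[DomainHit]:
    """Scan one protein against every model; greedy non-overlap resolution.

    Candidate windows with identity >= the model threshold are accepted in
    order of descending identity (ties: smaller start, then token name),
    discarding any window overlapping an already-accepted one.  The result is
    sorted by start.  A protein shorter than every model yields an empty list.
    """
    if not models:
        raise ValueError("models must be non-empty")
    candidates: list[tuple[float, int, str, int]] = []
    for model in models:
        ident = _window_identities(sequence, model.consensus)
        m = len(model.consensus)
        for off in np.flatnonzero(ident >= model.min_identity):
            candidates.append((float(ident[off]), int(off) + 1, model.name, m))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    accepted: list[DomainHit] = []
    occupied: list[tuple[int, int]] = []
    for identity, start, token, m in candidates:
        end = start + m - 1
        if any(start <= e and end >= s for s, e in occupied):
            continue
        occupied.append((start, end))
        accepted.append(DomainHit(protein_id, token, start, end, identity))
    accepted.sort(key=lambda h: h.start)
    return accepted


def build_architecture(
    hits: Sequence[DomainHit], mld_gap: int = DEFAULT_MLD_GAP
) -> list[str]:
    """Ordered token string; adjacent MD pairs within *mld_gap* collapse to MLD.

    The collapse is pairwise left-to-right: MD MD MD -> MLD MD.  Input must be
    sorted by start and non-overlapping.
    """
    for prev, cur in zip(hits, hits[1:]):
        if cur.start < prev.start:
            raise ValueError("hits must be sorted by start")
        if cur.start <= prev.end:
            raise ValueError(f"overlapping hits at {prev.end} / {cur.start}")
    out: list[tuple[str, int, int]] = []
    for hit in hits:
        if (
            hit.token == "MD"
            and out
            and out[-1][0] == "MD"
            and hit.start - out[-1][2] - 1 <= mld_gap
        ):
            out[-1] = ("MLD", out[-1][1], hit.end)
        else:
            out.append((hit.token, hit.start, hit.end))
    return [token for token, _, _ in out]


def _has_order(tokens: Sequence[str], pattern: Sequence[str]) -> bool:
    """True if *pattern* occurs as a subsequence of *tokens*."""
    it = iter(tokens)
    return all(any(t == p for t in it) for p in pattern)


def classify_superclade(tokens: Sequence[str]) -> str:
    """Apply the superclade rules in order; SP/TMD/CC are ignored.

    Total function: anything not matching a rule is ``Unclassified``.
    """
    core = [t for t in tokens if t not in _NEUTRAL_TOKENS]
    if _has_order(core, ("LRR", "MD", "PK")):
        return "LRR-MD-PK"
    if _has_order(core, ("MLD", "LRR", "PK")):
        return "MLD-LRR-PK"
    if "MLD" in core and "PK" in core and "LRR" not in core:
        return "MLD-PK"
    if "MLD" in core and "LRR" in core and "PK" not in core:
        return "MLD-LRR"
    if "MD" in core and "Kin" in core:
        return "MD-Kin"
    return "Unclassified"


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da (residue masses plus one water).

    Unknown residues (e.g. X) contribute the mean residue mass.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return (
        sum(_RESIDUE_MASS.get(aa, _MEAN_RESIDUE_MASS) for aa in sequence) + _WATER_MASS
    )


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at *ph* using the fixed EMBOSS pKa set.

    Henderson–Hasselbalch per ionizable group plus the two termini.
    """
    if not sequence:
        raise ValueError("empty sequence")
    charge = 1.0 / (1.0 + 10 ** (ph - _PKA_POSITIVE["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (_PKA_NEGATIVE["Cterm"] - ph))
    for aa, pka in _PKA_POSITIVE.items():
        if aa == "Nterm":
            continue
        n = sequence.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka))
    for aa, pka in _PKA_NEGATIVE.items():
        if aa == "Cterm":
            continue
        n = sequence.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka - ph))
    return charge


def isoelectric_point(sequence: str, tol: float = 0.01) -> float:
    """pH at which the net charge is zero, by bisection over [0, 14]."""
    lo, hi = 0.0, 14.0
    # net_charge is strictly decreasing in pH
    while hi - lo > tol / 10:
        mid = (lo + hi) / 2
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def protein_properties(sequence: str) -> tuple[float, float]:
    """(molecular weight in Da, isoelectric point)."""
    return molecular_weight(sequence), isoelectric_point(sequence)


def annotate_proteins(
    proteins: Iterable[tuple[str, str]],
    models: Sequence[DomainModel],
    mld_gap: int = DEFAULT_MLD_GAP,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan, build architectures and classify a whole proteome.

    Parameters
    ----------
    proteins : iterable of (id, sequence)

    Returns
    -------
    architectures : DataFrame with columns protein, architecture, superclade
    hits : DataFrame with columns protein, token, start, end, identity
    """
    arch_rows, hit_rows = [], []
    for pid, seq in proteins:
        hits = scan_domains(pid, seq, models)
        tokens = build_architecture(hits, mld_gap=mld_gap)
        arch_rows.append(
            {
                "protein": pid,
                "architecture": "-".join(tokens),
                "superclade": classify_superclade(tokens),
            }
        )
        for h in hits:
            hit_rows.append(
                {
                    "protein": pid,
                    "token": h.token,
                    "start": h.start,
                    "end": h.end,
                    "identity": h.identity,
                }
            )
    hit_cols = ["protein", "token", "start", "end", "identity"]
    return (
        pd.DataFrame(arch_rows, columns=["protein", "architecture", "superclade"]),
        pd.DataFrame(hit_rows, columns=hit_cols),
    )


def architecture_from_hit_table(
    hits: pd.DataFrame, mld_gap: int = DEFAULT_MLD_GAP
) -> pd.DataFrame:
    """Build architectures from a precomputed hit table (e.g. hmmscan-derived).

    Expects columns protein, token, start, end and optionally identity.
    """
    rows = []
    for pid, grp in hits.groupby("protein", sort=True):
        grp = grp.sort_values("start")
        hit_objs = [
            DomainHit(pid, r.token, int(r.start), int(r.end), float(getattr(r, "identity", 1.0)))
            for r in grp.itertuples()
        ]
        tokens = build_architecture(hit_objs, mld_gap=mld_gap)
        rows.append(
            {
                "protein": pid,
                "architecture": "-".join(tokens),
                "superclade": classify_superclade(tokens),
            }
        )
    return pd.DataFrame(rows, columns=["protein", "architecture", "superclade"])
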
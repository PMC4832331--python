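"""Consensus profiles, the C-terminal β-sheet signature, and chimeras.

The C-terminal two-stranded β-sheet of the enterobacterial lysine
decarboxylases (regions 631–640 and 697 to the C-terminus in E. coli
LdcI numbering, inside the CTD 564–715) carries the residues that
determine RavA binding. Per-group consensus profiles over an alignment
give a position-specific log-odds classifier over those positions;
chimera design swaps the two regions between a backbone and a donor
sequence, emulating the LdcIC/LdcCI constructs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    AMINO_ACIDS,
    GAP,
    AlignmentError,
    MultipleAlignment,
    PairwiseAlignment,
    ReferenceMap,
    SequenceRecord,
    map_to_reference,
)

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Residue polarity classes used for profile colouring/reporting.
POLARITY_SCHEME: dict[str, str] = {
    **{a: "acidic" for a in "DE"},
    **{a: "basic" for a in "KRH"},
    **{a: "hydrophilic" for a in "STNQCGY"},
    **{a: "hydrophobic" for a in "AVLIPFMW"},
}

#: E. coli LdcI reference length (residues).
REFERENCE_LENGTH = 715


class SignatureError(ValueError):
    pass


@dataclass(frozen=True)
class SignatureDefinition:
    """Reference-numbering intervals of the two β-strand regions."""

    regions: tuple[tuple[int, int], ...] = ((631, 640), (697, REFERENCE_LENGTH))

    def __post_init__(self):
        last_end = 0
        for start, end in self.regions:
            if start < 1 or end < start:
                raise SignatureError(f"bad region ({start}, {end})")
            if start <= last_end:
                raise SignatureError("signature regions overlap or are unordered")
            last_end = end

    @property
    def positions(self) -> list[int]:
        return [p for s, e in self.regions for p in range(s, e + 1)]


@dataclass
class ConsensusProfile:
    """Per-column residue frequencies and conservation for one group."""

    group_id: str
    frequencies: np.ndarray  # L x 21 (20 residues + gap), rows sum to 1
    conservation: np.ndarray  # L, in [0, 1] (or bits if information mode)
    majority: list[str]
    mode: str = "frequency"

    @property
    def polarity(self) -> list[str]:
        return [POLARITY_SCHEME.get(m, "gap") for m in self.majority]

    def to_frame(self) -> pd.DataFrame:
        cols = list(AMINO_ACIDS) + ["gap"]
        df = pd.DataFrame(self.frequencies, columns=cols)
        df.insert(0, "column", np.arange(1, len(df) + 1))
        df["conservation"] = self.conservation
        df["majority"] = self.majority
        df["polarity"] = self.polarity
        return df


@dataclass
class SignatureProfile:
    """Per-signature-position frequencies for one group."""

    group_id: str
    positions: list[int]  # reference numbering
    frequencies: np.ndarray  # len(positions) x 21


@dataclass
class SignatureString:
    """Signature residues of one aligned row, with reference positions."""

    positions: list[int]
    residues: str
    gapped_positions: list[int] = field(default_factory=list)


def build_consensus(
    aln: MultipleAlignment,
    group_labels: dict[str, str] | None = None,
    mode: str = "frequency",
) -> dict[str, ConsensusProfile]:
    """Family-wide and per-group consensus profiles.

    Conservation is the majority-residue relative frequency (default)
    or Shannon information content in bits.
    """
    if mode not in {"frequency", "information"}:
        raise SignatureError(f"unknown conservation mode {mode!r}")
    groups: dict[str, list[str]] = {"family": list(aln.rows)}
    if group_labels:
        missing = [i for i in aln.ids if i not in group_labels]
        if missing:
            raise SignatureError(f"unlabelled records: {missing}")
        for rec_id, row in zip(aln.ids, aln.rows):
            groups.setdefault(group_labels[rec_id], []).append(row)
    out = {}
    for gid, rows in groups.items():
        if not rows:
            raise SignatureError(f"empty group {gid!r}")
        freq = _column_frequencies(rows)
        resfreq = freq[:, :20]
        maj_idx = resfreq.argmax(axis=1)
        majority = [
            AMINO_ACIDS[k] if resfreq[j, k] > 0 else GAP
            for j, k in enumerate(maj_idx)
        ]
        if mode == "frequency":
            cons = resfreq.max(axis=1)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                colsum = resfreq.sum(axis=1, keepdims=True)
                p = np.where(colsum > 0, resfreq / np.maximum(colsum, 1e-300), 0.0)
                h = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
            cons = np.where(colsum[:, 0] > 0, math.log2(20) - h, 0.0)
        out[gid] = ConsensusProfile(gid, freq, cons, majority, mode)
    return out


def _column_frequencies(rows: list[str]) -> np.ndarray:
    length = len(rows[0])
    freq = np.zeros((length, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c == GAP:
                freq[j, 20] += 1.0
            elif c == "X":
                freq[j, :20] += 1.0 / 20.0
            else:
                freq[j, _AA_INDEX[c]] += 1.0
    return freq / len(rows)


def extract_signature(
    row: str, refmap: ReferenceMap, sigdef: SignatureDefinition
) -> SignatureString:
    """Signature residues of one gapped alignment row.

    Positions whose reference residue falls in a signature region are
    read off the row; gap symbols are kept and flagged.
    """
    positions, chars, gapped = [], [], []
    unmapped = 0
    for pos in sigdef.positions:
        col = refmap.column_of.get(pos)
        if col is None:
            unmapped += 1
            continue
        c = row[col]
        positions.append(pos)
        chars.append(c)
        if c == GAP:
            gapped.append(pos)
    if not positions:
        raise SignatureError("signature regions entirely unmapped on reference")
    return SignatureString(positions, "".join(chars), gapped)


def build_signature_profiles(
    aln: MultipleAlignment,
    group_labels: dict[str, str],
    refmap: ReferenceMap,
    sigdef: SignatureDefinition = SignatureDefinition(),
) -> dict[str, SignatureProfile]:
    """Per-group signature-position frequency profiles."""
    by_group: dict[str, list[str]] = {}
    for rec_id, row in zip(aln.ids, aln.rows):
        sig = extract_signature(row, refmap, sigdef)
        by_group.setdefault(group_labels[rec_id], []).append(sig.residues)
    positions = extract_signature(aln.rows[0], refmap, sigdef).positions
    out = {}
    for gid, sigs in by_group.items():
        out[gid] = SignatureProfile(gid, positions, _column_frequencies(sigs))
    return out


def discriminating_positions(
    profiles: dict[str, SignatureProfile],
) -> list[int]:
    """Signature positions whose per-group majority residues are disjoint."""
    gids = sorted(profiles)
    if len(gids) != 2:
        raise SignatureError("discriminating positions need exactly 2 groups")
    a, b = (profiles[g] for g in gids)
    out = []
    for k, pos in enumerate(a.positions):
        maj_a = {AMINO_ACIDS[i] for i in np.flatnonzero(a.frequencies[k, :20] ==
                                                        a.frequencies[k, :20].max())
                 if a.frequencies[k, :20].max() > 0}
        maj_b = {AMINO_ACIDS[i] for i in np.flatnonzero(b.frequencies[k, :20] ==
                                                        b.frequencies[k, :20].max())
                 if b.frequencies[k, :20].max() > 0}
        if maj_a and maj_b and not (maj_a & maj_b):
            out.append(pos)
    return out


def classify_by_signature(
    signature: SignatureString,
    profiles: dict[str, SignatureProfile],
    pseudocount: float = 0.5,
    margin: float = 0.0,
) -> tuple[str, float]:
    """Log-odds classification of a signature string.

    Score of a group is sum over non-gap positions of
    log((freq + pseudocount/20-normalised) / background), background
    uniform 1/20. Returns (label, score difference between the best
    and the other group); "unknown" when |score| <= margin or the
    signature is all gaps.
    """
    gids = sorted(profiles)
    if len(gids) != 2:
        raise SignatureError("classification needs exactly 2 group profiles")
    loglik = {}
    for gid in gids:
        prof = profiles[gid]
        pos_index = {p: k for k, p in enumerate(prof.positions)}
        total = 0.0
        used = 0
        for pos, c in zip(signature.positions, signature.residues):
            if c == GAP or c == "X" or pos not in pos_index:
                continue
            k = pos_index[pos]
            f = prof.frequencies[k, _AA_INDEX[c]]
            p = (f + pseudocount / 20.0) / (1.0 + pseudocount)
            total += math.log(p / (1.0 / 20.0))
            used += 1
        loglik[gid] = (total, used)
    if all(used == 0 for _, used in loglik.values()):
        return "unknown", 0.0
    score = loglik[gids[0]][0] - loglik[gids[1]][0]
    if abs(score) <= margin:
        return "unknown", score
    return (gids[0] if score > 0 else gids[1]), score


# ---------------------------------------------------------------------------
# chimera design


@dataclass
class ChimeraJunction:
    region: tuple[int, int]
    backbone_span: tuple[int, int]
    donor_span: tuple[int, int]


@dataclass
class ChimeraResult:
    record: SequenceRecord
    junctions: list[ChimeraJunction]

    def junction_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(
                    region_start=j.region[0], region_end=j.region[1],
                    backbone_start=j.backbone_span[0], backbone_end=j.backbone_span[1],
                    donor_start=j.donor_span[0], donor_end=j.donor_span[1],
                )
                for j in self.junctions
            ]
        )


def design_chimera(
    backbone: SequenceRecord,
    donor: SequenceRecord,
    aln: PairwiseAlignment,
    sigdef: SignatureDefinition = SignatureDefinition(),
    chimera_id: str | None = None,
) -> ChimeraResult:
    """Swap the signature regions of the donor into the backbone.

    Regions are located on the backbone's own (1-based) numbering via
    the pairwise alignment. Inside a region the donor's aligned
    segment (including donor insertions) replaces the backbone
    segment; everything outside is byte-identical to the backbone.
    """
    if aln.a.id == backbone.id and aln.b.id == donor.id:
        brow, drow = aln.aligned_a, aln.aligned_b
    elif aln.b.id == backbone.id and aln.a.id == donor.id:
        brow, drow = aln.aligned_b, aln.aligned_a
    else:
        raise SignatureError("alignment does not contain backbone and donor")

    regions = sigdef.regions
    out: list[str] = []
    junctions: list[ChimeraJunction] = []
    bpos = dpos = 0
    reg_backbone: dict[tuple[int, int], list[int]] = {r: [] for r in regions}
    reg_donor: dict[tuple[int, int], list[int]] = {r: [] for r in regions}
    for bc, dc in zip(brow, drow):
        if bc != GAP:
            bpos += 1
        if dc != GAP:
            dpos += 1
        region = next(
            (r for r in regions if bc != GAP and r[0] <= bpos <= r[1]), None
        )
        if region is None and bc == GAP:
            # donor insertion: attach to a region only if strictly inside it
            region = next(
                (r for r in regions if r[0] <= bpos and bpos + 1 <= r[1]), None
            )
        if region is not None:
            if dc != GAP:
                out.append(dc)
                reg_donor[region].append(dpos)
            if bc != GAP:
                reg_backbone[region].append(bpos)
        elif bc != GAP:
            out.append(bc)
    for region in regions:
        if not reg_backbone[region]:
            raise SignatureError(
                f"region {region} lies outside the backbone sequence"
            )
        if not reg_donor[region]:
            raise SignatureError(
                f"donor is all-gaps across region {region}; chimera design failed"
            )
        junctions.append(
            ChimeraJunction(
                region,
                (min(reg_backbone[region]), max(reg_backbone[region])),
                (min(reg_donor[region]), max(reg_donor[region])),
            )
        )
    name = chimera_id or f"{backbone.id}+{donor.id}-sig"
    return ChimeraResult(SequenceRecord(name, "".join(out), backbone.taxon), junctions)


# ---------------------------------------------------------------------------
# logo plot (letter-stack rendering of a profile region)


def plot_signature_logo(
    profile: ConsensusProfile,
    refmap: ReferenceMap,
    sigdef: SignatureDefinition,
    path,
) -> None:
    """Write a simple conservation-scaled letter-stack logo (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "acidic": "red", "basic": "blue",
        "hydrophilic": "green", "hydrophobic": "black",
    }
    positions = [p for p in sigdef.positions if p in refmap.column_of]
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(positions)), 2.4))
    for x, pos in enumerate(positions):
        col = refmap.column_of[pos]
        freqs = profile.frequencies[col, :20]
        order = np.argsort(freqs)
        y = 0.0
        for k in order:
            f = freqs[k]
            if f < 0.01:
                continue
            aa = AMINO_ACIDS[k]
            ax.text(
                x, y + f / 2.0, aa,
                ha="center", va="center",
                fontsize=6 + 14 * f,
                color=colors[POLARITY_SCHEME[aa]],
            )
            y += f
    ax.set_xticks(range(len(positions)))
    ax.set_xticklabels(positions, rotation=90, fontsize=6)
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("frequency")
    ax.set_title(profile.group_id)
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)


def profiles_to_tsv(profiles: dict[str, ConsensusProfile], path) -> None:
    frames = []
    for gid, prof in profiles.items():
        df = prof.to_frame()
        df.insert(0, "group", gid)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
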
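"""End-to-end concordance analysis: context vs signature vs phylogeny.

The headline claim this pipeline checks: the genetic environment of an
enterobacterial lysine decarboxylase gene, the residues of its
C-terminal β-sheet, and its position in the family phylogeny all
induce the same two-group classification (ldcI-like vs ldcC-like).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import consensus as cs
from . import genome_context as gc
from . import phylo
from .alignment import (
    MultipleAlignment,
    SequenceRecord,
    map_to_reference,
    progressive_msa,
)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    reference_id: str | None = None  # default: first sequence
    signature_regions: tuple[tuple[int, int], ...] | None = None
    distance_model: str = "poisson"
    bootstrap_reps: int = 100
    pseudocount: float = 0.5
    margin: float = 0.0
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Flat key=value config file; unknown keys rejected."""
        cfg = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "reference_id":
                cfg.reference_id = value
            elif key == "signature_regions":
                parts = [p for p in value.replace(",", " ").split() if p]
                pairs = [tuple(map(int, p.split("-"))) for p in parts]
                cfg.signature_regions = tuple(pairs)  # e.g. "631-640 697-715"
            elif key == "distance_model":
                cfg.distance_model = value
            elif key == "bootstrap_reps":
                cfg.bootstrap_reps = int(value)
            elif key == "pseudocount":
                cfg.pseudocount = float(value)
            elif key == "margin":
                cfg.margin = float(value)
            elif key == "seed":
                cfg.seed = int(value)
            else:
                raise PipelineError(f"unknown config key {key!r}")
        return cfg


@dataclass
class ConcordanceReport:
    per_taxon: pd.DataFrame  # taxon, context_call, signature_call, tree_group
    context_vs_signature: float | None
    context_vs_tree: float | None
    signature_vs_tree: float | None
    tree_separable: bool
    separating_edge_support: float | None
    discordant_taxa: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                context_vs_signature=self.context_vs_signature,
                context_vs_tree=self.context_vs_tree,
                signature_vs_tree=self.signature_vs_tree,
                tree_separable=self.tree_separable,
                separating_edge_support=self.separating_edge_support,
                discordant_taxa=self.discordant_taxa,
                per_taxon=self.per_taxon.to_dict(orient="records"),
            ),
            indent=2,
        )


def _agreement(a: list[str], b: list[str]) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


def run_concordance(
    sequences: list[SequenceRecord],
    neighborhoods: list[gc.NeighborhoodRecord],
    config: PipelineConfig | None = None,
    alignment: MultipleAlignment | None = None,
    out_dir: str | Path | None = None,
) -> ConcordanceReport:
    """Run context -> MSA -> signature -> tree and compare groupings.

    Sequence ids must match the taxon field of the neighborhood
    records. Signature-group profiles are trained on the context
    calls (environment first, then sequence, as in the field practice),
    and each taxon is then classified leave-one-out by its signature.
    """
    if not sequences:
        raise PipelineError("no input sequences")
    cfg = config or PipelineConfig()
    by_taxon = {r.taxon: r for r in neighborhoods}
    seq_ids = [s.id for s in sequences]
    missing = sorted(set(seq_ids) ^ set(by_taxon))
    if missing:
        raise PipelineError(f"taxa mismatch between inputs: {missing}")

    # 1. genetic environment
    calls = gc.audit_annotations([by_taxon[t] for t in seq_ids])
    context_call = {
        t: c.call.replace("-like", "") for t, c in zip(seq_ids, calls)
    }
    context_group = {
        t: {"ldcI": "A", "ldcC": "B"}.get(context_call[t], "unknown")
        for t in seq_ids
    }

    # 2. alignment and reference map
    aln = alignment or progressive_msa(sequences)
    ref_id = cfg.reference_id or seq_ids[0]
    refmap = map_to_reference(aln, ref_id)
    sigdef = (
        cs.SignatureDefinition(cfg.signature_regions)
        if cfg.signature_regions
        else cs.SignatureDefinition(
            _fit_regions_to_reference(len(aln.degapped(ref_id)))
        )
    )

    # 3. signature classification (profiles from context groups, LOO)
    trainable = {t: g for t, g in context_group.items() if g in {"A", "B"}}
    if len(set(trainable.values())) < 2:
        raise PipelineError("context calls do not define two training groups")
    signature_group = {}
    for t in seq_ids:
        train_labels = {u: g for u, g in trainable.items() if u != t}
        # row subsetting keeps alignment columns, so the full refmap applies
        profiles = cs.build_signature_profiles(
            _subset(aln, list(train_labels)), train_labels, refmap, sigdef
        )
        sig = cs.extract_signature(aln.row(t), refmap, sigdef)
        label, _score = cs.classify_by_signature(
            sig, profiles, cfg.pseudocount, cfg.margin
        )
        signature_group[t] = label if label in {"A", "B"} else "unknown"

    # 4. tree and bipartition
    tree = phylo.bootstrap_supports(
        aln, cfg.distance_model, cfg.bootstrap_reps, cfg.seed
    )
    group_a = {t for t in seq_ids if signature_group[t] == "A"}
    group_b = {t for t in seq_ids if signature_group[t] == "B"}
    tree_group = {t: "unknown" for t in seq_ids}
    separable = False
    support = None
    if group_a and group_b and not (group_a | group_b) - set(seq_ids):
        if len(group_a | group_b) == len(seq_ids):
            separable = phylo.bipartition_separates(tree, group_a, group_b)
            if separable:
                for t in seq_ids:
                    tree_group[t] = "A" if t in group_a else "B"
                support = phylo.edge_support(tree, group_a, group_b)

    # 5. report
    per_taxon = pd.DataFrame(
        dict(
            taxon=seq_ids,
            context_group=[context_group[t] for t in seq_ids],
            signature_group=[signature_group[t] for t in seq_ids],
            tree_group=[tree_group[t] for t in seq_ids],
        )
    )
    ctx = per_taxon.context_group.tolist()
    sig_g = per_taxon.signature_group.tolist()
    tre = per_taxon.tree_group.tolist()
    report = ConcordanceReport(
        per_taxon=per_taxon,
        context_vs_signature=_agreement(ctx, sig_g),
        context_vs_tree=_agreement(ctx, tre) if separable else None,
        signature_vs_tree=_agreement(sig_g, tre) if separable else None,
        tree_separable=separable,
        separating_edge_support=support,
        discordant_taxa=sorted(
            t
            for t, a, b, c in zip(seq_ids, ctx, sig_g, tre)
            if len({a, b, c} - {"unknown"}) > 1
        ),
    )
    if out_dir is not None:
        _write_outputs(Path(out_dir), cfg, aln, tree, report)
    return report


def _fit_regions_to_reference(ref_len: int) -> tuple[tuple[int, int], ...]:
    """Default β-sheet regions, truncated to the reference length."""
    regions = []
    for start, end in ((631, 640), (697, 715)):
        if start <= ref_len:
            regions.append((start, min(end, ref_len)))
    if not regions:
        raise PipelineError(
            f"reference (length {ref_len}) does not cover the default "
            "signature regions; set signature_regions explicitly"
        )
    return tuple(regions)


def _subset(aln: MultipleAlignment, keep: list[str]) -> MultipleAlignment:
    idx = [aln.ids.index(k) for k in keep]
    return MultipleAlignment(
        [aln.ids[i] for i in idx],
        [aln.rows[i] for i in idx],
        [aln.taxa[i] for i in idx],
    )


def _write_outputs(out, cfg, aln, tree, report) -> None:
    from . import __version__
    from .alignment import write_alignment_fasta

    out.mkdir(parents=True, exist_ok=True)
    write_alignment_fasta(aln, out / "alignment.fasta")
    tree.write(path=str(out / "tree.nwk"), schema="newick")
    (out / "concordance.json").write_text(report.to_json())
    report.per_taxon.to_csv(out / "per_taxon.tsv", sep="\t", index=False)
    provenance = dict(
        tool="ldcsig",
        version=__version__,
        seed=cfg.seed,
        distance_model=cfg.distance_model,
        bootstrap_reps=cfg.bootstrap_reps,
        reference_id=cfg.reference_id,
    )
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
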
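"""Collapse technical phosphopeptide variants into quantified motifs.

Label-free phospho-quantification observes the same phosphorylation event
as many technical species: different charge states, missed tryptic
cleavages, and co-modifications such as oxidation or acetylation.  Merging
sums these species per (protein locus, exact phospho-site set), retaining
every unique phosphorylation event — a doubly-phosphorylated site set is a
distinct motif from its singly-phosphorylated subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import PhosphoMotif, PhosphoVariant


@dataclass
class MergeReport:
    n_variants_in: int = 0
    n_motifs_out: int = 0
    n_ambiguous_resolved: int = 0
    discarded: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_discarded(self) -> int:
        return sum(len(v) for v in self.discarded.values())

    def to_dict(self) -> dict:
        return {
            "n_variants_in": self.n_variants_in,
            "n_motifs_out": self.n_motifs_out,
            "n_ambiguous_resolved": self.n_ambiguous_resolved,
            "n_discarded": self.n_discarded,
            "discarded": self.discarded,
        }


def resolve_ambiguous_sites(
    variant: PhosphoVariant, predictions: list[dict]
) -> PhosphoVariant:
    """Confirm or correct a variant's site assignment by cross-referencing.

    Predictions are keyed by (peptide sequence, charge, co-modification
    count).  If a matching prediction exists, its site assignment replaces
    the variant's and the variant is flagged ``reassigned`` (or ``confirmed``
    when they already agree); otherwise the variant keeps its assignment and
    is flagged ``unconfirmed``.  When several predictions match, the one
    with the highest confidence wins; ties break toward the original
    assignment.
    """
    key = (variant.sequence, variant.charge, variant.n_mods)
    matches = [
        p
        for p in predictions
        if (p["sequence"], p["charge"], p.get("n_mods", 0)) == key
    ]
    out = PhosphoVariant(
        feature_id=variant.feature_id,
        locus=variant.locus,
        sequence=variant.sequence,
        charge=variant.charge,
        missed_cleavages=variant.missed_cleavages,
        modifications=variant.modifications,
        phospho_positions=variant.phospho_positions,
        abundance=variant.abundance,
        phospho_residues=variant.phospho_residues,
        localization=variant.localization,
        flags=set(variant.flags),
    )
    if not matches:
        out.flags.add("unconfirmed")
        return out
    best = max(matches, key=lambda p: p.get("confidence", 0.0))
    ties = [p for p in matches if p.get("confidence", 0.0) == best.get("confidence", 0.0)]
    if any(tuple(p["positions"]) == variant.phospho_positions for p in ties):
        out.flags.add("confirmed")
        return out
    predicted = tuple(sorted(best["positions"]))
    if predicted == variant.phospho_positions:
        out.flags.add("confirmed")
    else:
        out.phospho_positions = predicted
        out.flags.add("reassigned")
    return out


def merge_variants(
    variants: list[PhosphoVariant],
    predictions: list[dict] | None = None,
    ambiguous: str = "keep",
    drop_shared: bool = True,
) -> tuple[list[PhosphoMotif], MergeReport]:
    """Merge technical variants into uniquely keyed phosphopeptide motifs.

    Grouping key is (protein locus, exact set of phospho positions);
    abundances are summed per sample over group members, so total abundance
    is conserved apart from explicitly discarded variants.  Output order is
    deterministic: by locus, then site key.

    Parameters
    ----------
    predictions
        Optional alternative site predictions; when given, every variant is
        first passed through :func:`resolve_ambiguous_sites`.
    ambiguous
        ``keep`` (default) retains variants whose assignment could not be
        confirmed; ``drop`` discards them (reason ``unconfirmed``).
    drop_shared
        Discard variants mapping to multiple loci (reason ``shared``) to
        avoid double counting.
    """
    if ambiguous not in {"keep", "drop"}:
        raise ValueError(f"ambiguous policy must be 'keep' or 'drop', got {ambiguous!r}")
    report = MergeReport(n_variants_in=len(variants))
    # protein-sequence consistency per locus, when variants carry one
    seqs: dict[str, str] = {}
    kept: list[PhosphoVariant] = []
    for v in variants:
        if predictions is not None:
            v = resolve_ambiguous_sites(v, predictions)
            if "reassigned" in v.flags:
                report.n_ambiguous_resolved += 1
        if not v.phospho_positions:
            report.discarded.setdefault("no_phospho_site", []).append(v.feature_id)
            continue
        if drop_shared and ";" in v.locus:
            report.discarded.setdefault("shared", []).append(v.feature_id)
            continue
        if ambiguous == "drop" and "unconfirmed" in v.flags:
            report.discarded.setdefault("unconfirmed", []).append(v.feature_id)
            continue
        prot_seq = getattr(v, "protein_sequence", None)
        if prot_seq is not None:
            if seqs.setdefault(v.locus, prot_seq) != prot_seq:
                raise ValueError(f"conflicting protein sequence for locus {v.locus}")
        kept.append(v)

    groups: dict[tuple[str, tuple[int, ...]], list[PhosphoVariant]] = {}
    for v in kept:
        groups.setdefault(v.site_key, []).append(v)

    motifs = []
    for (locus, positions) in sorted(groups):
        members = groups[(locus, positions)]
        # min_count=1: a sample is present if any member quantified it
        total = pd.concat([m.abundance for m in members], axis=1).sum(axis=1, min_count=1)
        motifs.append(
            PhosphoMotif(
                locus=locus,
                positions=positions,
                abundance=total,
                members=tuple(sorted(m.feature_id for m in members)),
            )
        )
    report.n_motifs_out = len(motifs)
    return motifs, report


def motifs_to_table(motifs: list[PhosphoMotif]):
    """Assemble merged motifs into a QuantTable keyed ``locus@positions``."""
    from .io import QuantTable

    if not motifs:
        raise ValueError("no motifs to assemble")
    data = pd.DataFrame({m.motif_id: m.abundance for m in motifs}).T
    data.index.name = "feature_id"
    locus = pd.Series({m.motif_id: m.locus for m in motifs})
    return QuantTable(data, locus=locus)
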
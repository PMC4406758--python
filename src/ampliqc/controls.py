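"""Control-based contamination subtraction and reference-panel assignment.

Negative controls (extraction or PCR blanks) that yield sequence are the
only reliable evidence of contamination; OTUs "present" in a control are
removed from the samples.  Presence is configurable: exact centroid
equality, or co-membership at 97% identity (the default — contaminant
reads acquire sequencing errors too).  Taxonomic assignment is
best-identity against a user-supplied reference panel with the standard
genus (>= 97%) and family (>= 95%) similarity thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .clustering import OTU, identity
from .synthetic_data import ReferencePanel


def subtract_controls(
    sample_otus: Sequence[OTU],
    control_seqs: Sequence[str],
    mode: str = "cluster97",
) -> tuple[list[OTU], list[OTU], float]:
    """Remove sample OTUs present in control reactions.

    Returns (kept, removed, drop_pct) where drop_pct is the percentage of
    OTUs removed.  ``mode='exact'`` requires centroid equality to a control
    sequence; ``mode='cluster97'`` removes OTUs whose centroid is >= 97%
    identical to any control sequence.
    """
    if mode not in ("exact", "cluster97"):
        raise ValueError("mode must be 'exact' or 'cluster97'")
    kept: list[OTU] = []
    removed: list[OTU] = []
    for otu in sample_otus:
        if mode == "exact":
            hit = any(otu.centroid == c for c in control_seqs)
        else:
            hit = any(identity(otu.centroid, c) >= 0.97 for c in control_seqs)
        (removed if hit else kept).append(otu)
    drop_pct = 100.0 * len(removed) / len(sample_otus) if sample_otus else 0.0
    return kept, removed, drop_pct


def read_weighted_drop_pct(kept: Sequence[OTU], removed: Sequence[OTU]) -> float:
    """Proportion of reads (not OTUs) removed by control subtraction."""
    total = sum(o.abundance for o in kept) + sum(o.abundance for o in removed)
    return 100.0 * sum(o.abundance for o in removed) / total if total else 0.0


@dataclass(frozen=True)
class PanelAssignment:
    best_ref: str | None
    identity: float
    rank: str  # genus | family | none


def assign_to_panel(
    otus: Sequence[OTU],
    panel: ReferencePanel,
    genus_min: float = 0.97,
    family_min: float = 0.95,
) -> list[PanelAssignment]:
    """Best-identity assignment of each OTU centroid against the panel.

    Rank is genus at >= genus_min identity, family at >= family_min, else
    none.  Ties on identity resolve to the first panel record.
    """
    out: list[PanelAssignment] = []
    for otu in otus:
        best_ref, best_id = None, -1.0
        for rec in panel:
            ident = identity(otu.centroid, rec.sequence)
            if ident > best_id:
                best_ref, best_id = rec.id, ident
        if best_ref is None:
            out.append(PanelAssignment(None, 0.0, "none"))
            continue
        rank = "genus" if best_id >= genus_min else "family" if best_id >= family_min else "none"
        out.append(PanelAssignment(best_ref, best_id, rank))
    return out


def detection_table(
    samples: Mapping[str, Mapping[str, int]],
    replicates: Mapping[str, Sequence[str]] | None = None,
    min_replicates: int = 1,
) -> pd.DataFrame:
    """Per-taxon presence and percentage abundance per replicate.

    ``samples`` maps sample (replicate) id -> taxon -> assigned read count.
    ``replicates`` groups replicate ids (e.g. PCR triplicates of one
    extract); with ``min_replicates`` > 1 a taxon detected in fewer
    replicates of a group is flagged as excluded by the replicate
    criterion — the reporting convention that can silently drop genuinely
    present low-template taxa.
    """
    taxa = sorted({t for counts in samples.values() for t in counts})
    if replicates is None:
        replicates = {"all": list(samples)}
    rows = []
    for group, members in replicates.items():
        detections = {
            t: sum(1 for m in members if samples.get(m, {}).get(t, 0) > 0) for t in taxa
        }
        for member in members:
            counts = samples.get(member, {})
            total = sum(counts.values())
            for t in taxa:
                c = counts.get(t, 0)
                rows.append(
                    {
                        "group": group,
                        "replicate": member,
                        "taxon": t,
                        "reads": c,
                        "pct_abundance": 100.0 * c / total if total else 0.0,
                        "present": c > 0,
                        "excluded_by_replicate_criterion": (
                            0 < detections[t] < min_replicates
                        ),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "replicate", "taxon", "reads", "pct_abundance",
            "present", "excluded_by_replicate_criterion",
        ],
    )
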
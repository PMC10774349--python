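"""Cross-cohort signature transfer by exact subsequence matching.

Different 16S studies sequence different hypervariable regions at
different read lengths, so the same organism yields different ASVs in
each cohort. A short discovery ASV is declared present in a validation
cohort when its sequence occurs verbatim inside a (typically longer)
validation ASV. The counts of all validation ASVs containing a given
signature sequence are summed and treated as that signature feature's
abundance in the validation cohort.

A validation ASV containing two distinct signature sequences contributes
its counts to both aggregated columns (per-signature aggregation); such
shared containments are flagged in the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import AsvTable

logger = logging.getLogger(__name__)

__all__ = ["MatchReport", "match_signature", "reverse_complement"]

_RC = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class MatchReport:
    """Per-signature containment results and the aggregated reduced table."""

    matches: dict[str, list[str]]  # signature id -> containing validation ASV ids
    reduced_table: AsvTable | None  # columns = matched signature ids, summed counts
    shared_containments: dict[str, list[str]] = field(default_factory=dict)
    # validation ASV id -> signature ids it serves (only where > 1)

    @property
    def n_matched(self) -> int:
        return sum(1 for ids in self.matches.values() if ids)

    def matched_ids(self) -> list[str]:
        return [sig_id for sig_id, ids in self.matches.items() if ids]

    def presence(self) -> dict[str, str]:
        """Yes/No presence flag per signature id (published-table shape)."""
        return {s: ("Yes" if ids else "No") for s, ids in self.matches.items()}


def match_signature(
    signature_seqs: dict[str, str],
    validation: AsvTable,
    rc: bool = False,
) -> MatchReport:
    """Exact substring search of signature sequences in validation ASVs.

    Matching is case-insensitive on the forward strand; with ``rc=True``
    the reverse complement of each signature sequence is searched too, and
    a validation ASV hit on either orientation counts once. Counts of all
    containing validation ASVs are summed column-wise into the reduced
    table; unmatched signature ids are recorded but excluded from it.
    Signature sequences longer than every validation sequence cannot match
    and are warned about.
    """
    if not signature_seqs:
        raise ValueError("signature sequence set is empty")
    if validation.n_asvs == 0 or validation.n_samples == 0:
        raise ValueError("validation table is empty")

    queries = {k: v.strip().upper().replace("U", "T") for k, v in signature_seqs.items()}
    targets = [(a, validation.sequences[a].upper()) for a in validation.asv_ids]
    max_target = max(len(t) for _, t in targets)

    matches: dict[str, list[str]] = {}
    for sig_id, seq in queries.items():
        if len(seq) > max_target:
            logger.warning(
                "signature %s (%d nt) is longer than every validation ASV; cannot match",
                sig_id,
                len(seq),
            )
            matches[sig_id] = []
            continue
        probes = [seq, reverse_complement(seq)] if rc else [seq]
        matches[sig_id] = [
            asv_id for asv_id, target in targets if any(p in target for p in probes)
        ]

    usage: dict[str, list[str]] = {}
    for sig_id, ids in matches.items():
        for v in ids:
            usage.setdefault(v, []).append(sig_id)
    shared = {v: sigs for v, sigs in usage.items() if len(sigs) > 1}
    if shared:
        logger.info(
            "%d validation ASV(s) contain more than one signature sequence; "
            "their counts contribute to each matched column",
            len(shared),
        )

    matched_ids = [s for s, ids in matches.items() if ids]
    reduced = None
    if matched_ids:
        frame = validation.counts_frame()
        cols = np.column_stack(
            [frame[matches[s]].sum(axis=1).to_numpy() for s in matched_ids]
        )
        reduced = AsvTable(
            sample_ids=list(validation.sample_ids),
            asv_ids=matched_ids,
            counts=cols,
            sequences={s: queries[s] for s in matched_ids},
            labels=dict(validation.labels),
        )
    return MatchReport(matches=matches, reduced_table=reduced, shared_containments=shared)
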
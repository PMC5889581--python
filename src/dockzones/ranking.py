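"""Similarity scoring of contact zones against a primary configuration.

The score compares a configuration's contact zone with the primary zone:
+1 per shared reference-side contact residue, +4 per shared contact pair,
-1 per primary pair missing from the compared zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .contacts import ContactZone
from .errors import ValidationError
from .structures_io import Ensemble

__all__ = ["SimilarityScore", "similarity_score", "rank_configurations"]

RESIDUE_MATCH_WEIGHT = 1
PAIR_MATCH_WEIGHT = 4
MISSING_PAIR_WEIGHT = -1


@dataclass(frozen=True)
class SimilarityScore:
    config_id: str
    residue_matches: int
    pair_matches: int
    missing_pairs: int

    @property
    def score(self) -> int:
        return (
            RESIDUE_MATCH_WEIGHT * self.residue_matches
            + PAIR_MATCH_WEIGHT * self.pair_matches
            + MISSING_PAIR_WEIGHT * self.missing_pairs
        )


def similarity_score(compared: ContactZone, primary: ContactZone) -> SimilarityScore:
    """Score ``compared`` against ``primary``.

    Residue matches count reference-side residues only; pair matches require
    both residue keys to agree; each primary pair absent from the compared
    zone subtracts one.  Extra pairs in the compared zone are unpenalized.
    """
    if compared.reference_side != primary.reference_side:
        raise ValidationError(
            "zones use different reference-side conventions: "
            f"{compared.reference_side!r} vs {primary.reference_side!r}"
        )
    residue_matches = len(compared.ref_residues & primary.ref_residues)
    pair_matches = len(compared.pair_keys & primary.pair_keys)
    missing = len(primary.pair_keys - compared.pair_keys)
    return SimilarityScore(compared.config_id, residue_matches, pair_matches, missing)


def rank_configurations(
    ensemble: Ensemble,
    primary_zone: ContactZone,
    zones: Mapping[str, ContactZone],
) -> list[SimilarityScore]:
    """Order the ensemble by similarity to the primary configuration.

    The primary (if a member of the ensemble) comes first, then descending
    score with ties broken by ensemble input order (stable sort).
    """
    missing_ids = [c.id for c in ensemble if c.id not in zones]
    if missing_ids:
        raise ValidationError(f"no contact zone supplied for configurations: {missing_ids}")

    scored = [similarity_score(zones[conf.id], primary_zone) for conf in ensemble]
    head = [s for s in scored if s.config_id == primary_zone.config_id]
    rest = [s for s in scored if s.config_id != primary_zone.config_id]
    rest.sort(key=lambda s: -s.score)  # Python sort is stable: input order breaks ties
    return head + rest
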
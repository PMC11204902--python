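"""Align published score variants and weights to the target panel.

A published scoring file states, per variant, an effect allele, usually an
other allele, and a weight.  The panel states ref/alt and ALT dosages.  Four
resolvable orientations exist:

==================  ==========================================  ===========
action              condition                                   weight
==================  ==========================================  ===========
exact               (effect, other) == (alt, ref)               unchanged
switched            (effect, other) == (ref, alt)               negated
flipped             complement(effect, other) == (alt, ref)     unchanged
flipped_switched    complement(effect, other) == (ref, alt)     negated
==================  ==========================================  ===========

Palindromic allele pairs ({A,T} or {C,G}) are strand-unresolvable and are
dropped by default.  Score variants absent from the panel are replaced by
the best LD proxy with r-squared above a threshold (default 0.8, strict)
within a base-pair window, or dropped when none qualifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from prscad.data_io import GenotypePanel, ScoreSet, ScoreVariant, VALID_ALLELES

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC = ({"A", "T"}, {"C", "G"})

USED_ACTIONS = frozenset({"exact", "switched", "flipped", "flipped_switched", "proxied"})


@dataclass(frozen=True)
class MatchOutcome:
    """Audit entry for one source score variant."""

    action: str
    panel_variant_key: tuple[str, int] | None = None
    aligned_weight: float | None = None
    proxy_r2: float | None = None
    reason: str | None = None

    def __post_init__(self):
        if (self.aligned_weight is not None) != (self.action in USED_ACTIONS):
            raise ValueError("aligned_weight present iff action is a used action")
        if (self.proxy_r2 is not None) != (self.action == "proxied"):
            raise ValueError("proxy_r2 present iff action == proxied")


@dataclass
class HarmonizedScore:
    pgs_id: str
    entries: list[tuple[ScoreVariant, MatchOutcome]]

    @property
    def n_used(self) -> int:
        return sum(1 for _, o in self.entries if o.action in USED_ACTIONS)

    @property
    def n_dropped(self) -> int:
        return len(self.entries) - self.n_used

    def used(self) -> list[tuple[ScoreVariant, MatchOutcome]]:
        return [(v, o) for v, o in self.entries if o.action in USED_ACTIONS]

    def action_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, o in self.entries:
            counts[o.action] = counts.get(o.action, 0) + 1
        return counts

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("variant_id\taction\tpanel_key\taligned_weight\tproxy_r2\treason\n")
            for v, o in self.entries:
                key = "" if o.panel_variant_key is None else \
                    f"{o.panel_variant_key[0]}:{o.panel_variant_key[1]}"
                fh.write("\t".join([
                    v.variant_id, o.action, key,
                    "" if o.aligned_weight is None else repr(o.aligned_weight),
                    "" if o.proxy_r2 is None else f"{o.proxy_r2:.6f}",
                    o.reason or "",
                ]) + "\n")


class LDReference:
    """Pairwise r-squared between panel variants, computed lazily from dosages.

    An explicit ``pairs`` mapping {(key_a, key_b): r2} can be supplied (e.g.
    from an external LD panel); otherwise r-squared is the squared Pearson
    correlation between dosage columns of the target panel itself.
    """

    def __init__(self, panel: GenotypePanel | None = None,
                 pairs: dict | None = None, window_bp: int = 500_000):
        if panel is None and pairs is None:
            raise ValueError("LDReference needs a panel or explicit pairs")
        self.panel = panel
        self.pairs = pairs
        self.window_bp = window_bp
        self._pos_idx: dict | None = None

    def covers(self, key: tuple[str, int]) -> bool:
        """Whether this reference has any LD information for ``key``."""
        if self.pairs is not None and any(key in pair for pair in self.pairs):
            return True
        if self.panel is not None:
            if self._pos_idx is None:
                self._pos_idx = self.panel.position_index()
            return key in self._pos_idx
        return False

    def r2(self, key_a: tuple[str, int], key_b: tuple[str, int]) -> float | None:
        """r-squared between two variant keys, or None when unknown.

        Explicit pairs take precedence; otherwise the squared dosage
        correlation in the attached panel (requires both variants present).
        """
        if key_a == key_b:
            return 1.0
        if self.pairs is not None:
            v = self.pairs.get((key_a, key_b))
            if v is None:
                v = self.pairs.get((key_b, key_a))
            if v is not None or self.panel is None:
                return v
        if self._pos_idx is None:
            self._pos_idx = self.panel.position_index()
        ja, jb = self._pos_idx.get(key_a), self._pos_idx.get(key_b)
        if ja is None or jb is None:
            return None
        return self._column_r2(ja, jb)

    def _column_r2(self, ja: int, jb: int) -> float:
        a = self.panel.dosage[:, ja].astype(float).copy()
        b = self.panel.dosage[:, jb].astype(float).copy()
        ok = ~(self.panel.missing_mask[:, ja] | self.panel.missing_mask[:, jb])
        a, b = a[ok], b[ok]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            return 0.0
        r = np.corrcoef(a, b)[0, 1]
        return float(r * r)


@dataclass(frozen=True)
class _ProxyCandidate:
    r2: float
    dist: int
    pos: int
    col: int


def classify_alleles(effect: str, other: str, ref: str, alt: str) -> str:
    """Classify a score variant's allele pair against panel ref/alt."""
    for a in (effect, other, ref, alt):
        if a not in VALID_ALLELES:
            raise ValueError(f"invalid allele {a!r}")
    if effect == other or ref == alt:
        raise ValueError("allele pair members must differ")
    if {effect, other} in PALINDROMIC:
        return "ambiguous_dropped"
    if (effect, other) == (alt, ref):
        return "exact"
    if (effect, other) == (ref, alt):
        return "switched"
    ce, co = COMPLEMENT[effect], COMPLEMENT[other]
    if (ce, co) == (alt, ref):
        return "flipped"
    if (ce, co) == (ref, alt):
        return "flipped_switched"
    return "dropped"


def align_weight(weight: float, action: str) -> float:
    """Orient a published weight to ALT-dosage: negate on allele switch."""
    if action in ("exact", "flipped"):
        return weight
    if action in ("switched", "flipped_switched"):
        return -weight
    raise ValueError(f"align_weight: cannot align action {action!r}")


def _classify_one_allele(effect: str, ref: str, alt: str) -> str:
    """Effect-allele-only matching when the score file omits other_allele.

    Strand flips are unverifiable with a single allele, so only direct
    exact/switched matches are attempted.
    """
    if {effect, COMPLEMENT[effect]} & {ref, alt} == {ref, alt}:
        # effect allele and its complement are the panel pair: unresolvable
        return "ambiguous_dropped"
    if effect == alt:
        return "exact"
    if effect == ref:
        return "switched"
    return "dropped"


def find_proxy(score_variant: ScoreVariant, panel: GenotypePanel,
               ld_ref: LDReference, r2_min: float = 0.8,
               window_bp: int | None = None,
               palindromic_policy: str = "drop") -> MatchOutcome:
    """Best-LD substitution for a score variant absent from the panel.

    Candidates are panel variants within ``window_bp`` of the score
    variant's position with r-squared strictly above ``r2_min``; the highest
    r-squared wins, ties broken by smallest position distance then lowest
    position.  The winner's ref/alt are re-classified against the score
    variant's alleles to orient the weight.
    """
    if window_bp is None:
        window_bp = ld_ref.window_bp
    if score_variant.chrom is None or score_variant.pos is None:
        return MatchOutcome(action="dropped", reason="no_position")
    key = (str(score_variant.chrom), int(score_variant.pos))
    meta = panel.variant_meta
    cands = []
    for col, (c, p) in enumerate(zip(meta["chrom"], meta["pos"])):
        if str(c) != key[0]:
            continue
        dist = abs(int(p) - key[1])
        if dist == 0 or dist > window_bp:
            continue
        r2 = ld_ref.r2(key, (str(c), int(p)))
        if r2 is None:
            continue
        if r2 > r2_min:
            cands.append(_ProxyCandidate(r2=r2, dist=dist, pos=int(p), col=col))
    if not cands:
        return MatchOutcome(action="dropped",
                            reason="no_proxy" if ld_ref.covers(key) else "no_ld_data")
    best = min(cands, key=lambda c: (-c.r2, c.dist, c.pos))
    row = meta.iloc[best.col]
    if score_variant.other_allele is None:
        sub = _classify_one_allele(score_variant.effect_allele, row["ref"], row["alt"])
    else:
        sub = classify_alleles(score_variant.effect_allele, score_variant.other_allele,
                               row["ref"], row["alt"])
        if sub == "ambiguous_dropped" and palindromic_policy == "assume_same_strand":
            sub = _classify_same_strand(score_variant.effect_allele,
                                        score_variant.other_allele,
                                        row["ref"], row["alt"])
    if sub not in ("exact", "switched", "flipped", "flipped_switched"):
        return MatchOutcome(action="dropped", reason=f"proxy_alleles_{sub}")
    return MatchOutcome(
        action="proxied",
        panel_variant_key=(str(row["chrom"]), int(row["pos"])),
        aligned_weight=align_weight(score_variant.weight, sub),
        proxy_r2=best.r2,
    )


def _classify_same_strand(effect, other, ref, alt) -> str:
    """Palindromic pair resolved by assuming score and panel share a strand."""
    if (effect, other) == (alt, ref):
        return "exact"
    if (effect, other) == (ref, alt):
        return "switched"
    return "dropped"


def harmonize_scoreset(scoreset: ScoreSet, panel: GenotypePanel,
                       ld_ref: LDReference | None = None, r2_min: float = 0.8,
                       window_bp: int = 500_000,
                       palindromic_policy: str = "drop") -> HarmonizedScore:
    """Map every source variant to exactly one :class:`MatchOutcome`.

    Matching is primarily by (chrom, pos); rsID is the fallback key when the
    score file lacks positions.  Two source variants can never resolve to
    the same panel column (the second becomes ``dropped``).  Deterministic
    given identical inputs.
    """
    if ld_ref is None:
        ld_ref = LDReference(panel=panel, window_bp=window_bp)
    pos_idx = panel.position_index()
    id_idx = panel.id_index()
    meta = panel.variant_meta
    entries = []
    taken: set[tuple[str, int]] = set()
    for sv in scoreset.variants:
        col = None
        if sv.chrom is not None and sv.pos is not None:
            col = pos_idx.get((str(sv.chrom), int(sv.pos)))
        if col is None and sv.chrom is None:
            col = id_idx.get(sv.variant_id)
        if col is None:
            outcome = find_proxy(sv, panel, ld_ref, r2_min=r2_min,
                                 window_bp=window_bp,
                                 palindromic_policy=palindromic_policy)
        else:
            row = meta.iloc[col]
            if sv.other_allele is None:
                action = _classify_one_allele(sv.effect_allele, row["ref"], row["alt"])
            else:
                action = classify_alleles(sv.effect_allele, sv.other_allele,
                                          row["ref"], row["alt"])
                if action == "ambiguous_dropped" and palindromic_policy == "assume_same_strand":
                    resolved = _classify_same_strand(sv.effect_allele, sv.other_allele,
                                                     row["ref"], row["alt"])
                    action = resolved if resolved != "dropped" else "ambiguous_dropped"
            key = (str(row["chrom"]), int(row["pos"]))
            if action in ("exact", "switched", "flipped", "flipped_switched"):
                outcome = MatchOutcome(
                    action=action, panel_variant_key=key,
                    aligned_weight=align_weight(sv.weight, action),
                )
            elif action == "ambiguous_dropped":
                outcome = MatchOutcome(action="ambiguous_dropped", reason="palindromic")
            else:
                outcome = MatchOutcome(action="dropped", reason="allele_mismatch")
        if outcome.action in USED_ACTIONS:
            if outcome.panel_variant_key in taken:
                outcome = MatchOutcome(action="dropped", reason="duplicate_target")
            else:
                taken.add(outcome.panel_variant_key)
        entries.append((sv, outcome))
    score = HarmonizedScore(pgs_id=scoreset.pgs_id, entries=entries)
    logger.info("%s: harmonized %d variants: %s", scoreset.pgs_id,
                len(entries), score.action_counts())
    return score
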
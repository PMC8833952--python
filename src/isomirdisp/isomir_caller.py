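"""isomiR calling: ungapped read placement on hairpins, isoform annotation,
variant labeling, terminal-SNV filtering, and 16-category classification.

Conventions
-----------
* offset5: + means the 5' end is trimmed relative to the canonical mature,
  - means extended.
* offset3: + means the read's 3' terminus lies beyond the canonical 3' end
  (templated extension and/or non-templated addition), - means trimmed.
* SNV positions are always reported on the canonical mature coordinate
  system (1-based), so seed position 3 means the same thing for every
  isoform of a mature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .reference_io import (
    Hairpin,
    MatureAnnotation,
    ReferenceBundle,
    SEED_END,
    SEED_START,
    VariantRecord,
)

__all__ = [
    "PlacementConfig",
    "ReadPlacement",
    "SNV",
    "IsomirCall",
    "place_read",
    "call_isomir",
    "annotate_variants",
    "filter_terminal_unannotated",
    "classify_isomir",
    "category_table",
    "isomir_name",
    "parse_isomir_name",
    "call_from_name",
    "call_reads",
]

MIN_READ_LEN = 15

SHIFT_CLASSES = ("NO_SHIFT", "SHIFT5", "SHIFT3", "SHIFT53")
VARIANT_LABELS = ("NONE", "DNA_VARIANT", "EDITING", "UNKNOWN")


@dataclass(frozen=True)
class PlacementConfig:
    max_mismatches: int = 2
    max_nta: int = 3
    min_aligned_len: int = MIN_READ_LEN


@dataclass(frozen=True)
class ReadPlacement:
    read_seq: str
    hairpin_id: str
    start: int  # 0-based on hairpin
    aligned_len: int
    mismatches: tuple[tuple[int, str, str], ...]  # (pos_on_read 1-based, ref, alt)
    overhang3: str

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned region on the hairpin."""
        return self.start + self.aligned_len


@dataclass(frozen=True)
class SNV:
    pos_on_mature: int  # 1-based on the canonical mature; may be <1 or >len
    ref: str
    alt: str
    annotation: str = "UNKNOWN"  # EDITING | DNA_VARIANT | UNKNOWN

    @property
    def in_seed(self) -> bool:
        return SEED_START <= self.pos_on_mature <= SEED_END


@dataclass(frozen=True)
class IsomirCall:
    mature_name: str
    offset5: int
    offset3: int
    templated3: bool
    nta_seq: str
    snvs: tuple[SNV, ...]
    aligned_len: int
    count: int = 1

    def __post_init__(self) -> None:
        # canonical SNV order so calls compare/name deterministically
        object.__setattr__(
            self,
            "snvs",
            tuple(sorted(self.snvs, key=lambda s: (s.pos_on_mature, s.ref, s.alt))),
        )

    @property
    def shift_class(self) -> str:
        s5 = self.offset5 != 0
        s3 = self.offset3 != 0 or bool(self.nta_seq)
        if s5 and s3:
            return "SHIFT53"
        if s5:
            return "SHIFT5"
        if s3:
            return "SHIFT3"
        return "NO_SHIFT"

    @property
    def variant_class(self) -> frozenset[str]:
        if not self.snvs:
            return frozenset({"NONE"})
        return frozenset(s.annotation for s in self.snvs)

    @property
    def is_canonical(self) -> bool:
        return (
            self.offset5 == 0
            and self.offset3 == 0
            and not self.snvs
            and not self.nta_seq
        )

    @property
    def name(self) -> str:
        return isomir_name(self)


# ---------------------------------------------------------------------------
# placement


def _score_at(read: str, hp: str, start: int, cfg: PlacementConfig):
    """Best alignment of `read` at hairpin offset `start`.

    Maximizes the aligned prefix length subject to: the last aligned base
    matches the hairpin (trailing mismatches become 3' overhang), internal
    mismatches <= max_mismatches, and overhang length <= max_nta.
    Returns (aligned_len, mismatches) or None.
    """
    n = len(read)
    room = len(hp) - start
    mms: list[tuple[int, str, str]] = []
    best = None
    limit = min(n, room)
    n_mm = 0
    for m in range(1, limit + 1):
        if read[m - 1] != hp[start + m - 1]:
            n_mm += 1
            mms.append((m, hp[start + m - 1], read[m - 1]))
            continue
        # last aligned base matches here
        if n_mm <= cfg.max_mismatches and n - m <= cfg.max_nta:
            best = (m, tuple(mms))
    return best


def _candidate_starts(read: str, hp: str, cfg: PlacementConfig) -> set[int]:
    """Exact-seed candidate placement starts.

    The first ``min_aligned_len`` bases are split into ``max_mismatches + 1``
    chunks; any placement with <= max_mismatches internal mismatches leaves
    at least one chunk mismatch-free (pigeonhole), so exact substring search
    of every chunk enumerates all qualifying starts.
    """
    k = cfg.min_aligned_len
    n_chunks = cfg.max_mismatches + 1
    size = max(1, k // n_chunks)
    starts: set[int] = set()
    for i in range(n_chunks):
        lo = i * size
        hi = k if i == n_chunks - 1 else (i + 1) * size
        chunk = read[lo:hi]
        pos = hp.find(chunk)
        while pos != -1:
            if pos - lo >= 0:
                starts.add(pos - lo)
            pos = hp.find(chunk, pos + 1)
    return starts


def place_read(
    read: str,
    hairpins: Mapping[str, Hairpin],
    config: PlacementConfig | None = None,
) -> ReadPlacement | None:
    """Best ungapped placement of a read across all hairpins.

    Ties are broken by (longest aligned prefix, fewest mismatches, leftmost
    start, lexicographically smallest hairpin id). Returns None when no
    placement satisfies the mismatch/overhang/length constraints.
    """
    cfg = config or PlacementConfig()
    read = read.upper().replace("U", "T")
    if not read:
        raise ValueError("empty read")
    if len(read) < MIN_READ_LEN:
        return None

    best_key = None
    best = None
    for hid in sorted(hairpins):
        hp = hairpins[hid].sequence
        for start in sorted(_candidate_starts(read, hp, cfg)):
            if len(hp) - start < cfg.min_aligned_len:
                continue
            scored = _score_at(read, hp, start, cfg)
            if scored is None:
                continue
            alen, mms = scored
            if alen < cfg.min_aligned_len:
                continue
            key = (-alen, len(mms), start, hid)
            if best_key is None or key < best_key:
                best_key = key
                best = ReadPlacement(
                    read_seq=read,
                    hairpin_id=hid,
                    start=start,
                    aligned_len=alen,
                    mismatches=mms,
                    overhang3=read[alen:],
                )
    return best


# ---------------------------------------------------------------------------
# calling


def _assign_mature(
    placement: ReadPlacement, matures: Iterable[MatureAnnotation]
) -> MatureAnnotation | None:
    """Unique mature overlapped by >= 50% of the mature length, else None."""
    hits = []
    for m in matures:
        if m.hairpin_id != placement.hairpin_id:
            continue
        ov = min(placement.end, m.end) - max(placement.start, m.start)
        if ov * 2 >= len(m):
            hits.append(m)
    return hits[0] if len(hits) == 1 else None


def call_isomir(
    placement: ReadPlacement,
    matures: Iterable[MatureAnnotation],
    hairpins: Mapping[str, Hairpin],
) -> IsomirCall | None:
    """Derive the isoform annotation of a placed read.

    Returns None for placements overlapping zero or more than one mature
    (callers should count those as unassigned).
    """
    mature = _assign_mature(placement, matures)
    if mature is None:
        return None

    offset5 = placement.start - mature.start
    templ3 = placement.end - mature.end  # templated part of the 3' offset
    nta = placement.overhang3
    offset3 = templ3 + len(nta)
    snvs = tuple(
        SNV(
            pos_on_mature=(placement.start + p - 1 - mature.start) + 1,
            ref=ref,
            alt=alt,
        )
        for p, ref, alt in placement.mismatches
    )
    return IsomirCall(
        mature_name=mature.name,
        offset5=offset5,
        offset3=offset3,
        templated3=not nta,
        nta_seq=nta,
        snvs=snvs,
        aligned_len=placement.aligned_len,
    )


def annotate_variants(
    call: IsomirCall, table: Sequence[VariantRecord]
) -> IsomirCall:
    """Label each SNV from the annotation table.

    EDITING requires an EDITING record at that mature position with A>G;
    DNA_VARIANT requires an exact (pos, ref, alt) match of a SNP or SOMATIC
    record. Anything else stays UNKNOWN — sequence alone never proves
    editing.
    """
    by_pos: dict[int, list[VariantRecord]] = {}
    for v in table:
        if v.mature_name == call.mature_name:
            by_pos.setdefault(v.pos_on_mature, []).append(v)

    new = []
    for s in call.snvs:
        ann = "UNKNOWN"
        for v in by_pos.get(s.pos_on_mature, []):
            if v.var_class == "EDITING" and (s.ref, s.alt) == ("A", "G"):
                ann = "EDITING"
                break
            if v.var_class in ("SNP", "SOMATIC") and (v.ref, v.alt) == (s.ref, s.alt):
                ann = "DNA_VARIANT"
        new.append(replace(s, annotation=ann))
    return replace(call, snvs=tuple(new))


def filter_terminal_unannotated(
    calls: Iterable[IsomirCall],
) -> tuple[list[IsomirCall], list[IsomirCall]]:
    """Discard calls with an UNKNOWN SNV in the first or last two aligned
    nucleotides of the read; keep everything else."""
    kept, discarded = [], []
    for c in calls:
        bad = False
        for s in c.snvs:
            if s.annotation != "UNKNOWN":
                continue
            pos_on_read = s.pos_on_mature - c.offset5
            if pos_on_read <= 2 or pos_on_read >= c.aligned_len - 1:
                bad = True
                break
        (discarded if bad else kept).append(c)
    return kept, discarded


def classify_isomir(call: IsomirCall) -> tuple[str, frozenset[str]]:
    """Shift class x variant-label set (one cell per distinct SNV label)."""
    return call.shift_class, call.variant_class


def category_table(calls: Iterable[IsomirCall]) -> dict[tuple[str, str], int]:
    """4x4 category counts; a multi-label call increments one cell per
    distinct variant label."""
    table = {(s, v): 0 for s in SHIFT_CLASSES for v in VARIANT_LABELS}
    for c in calls:
        shift, labels = classify_isomir(c)
        for v in labels:
            table[(shift, v)] += c.count
    return table


# ---------------------------------------------------------------------------
# nomenclature

_NAME_RE = re.compile(
    r"^(?P<mature>.+)\|5p(?P<o5>-?\d+)\|3p(?P<o3>-?\d+)\|nta:(?P<nta>[ACGT]+|-)\|"
    r"(?P<snvs>-|snv:.+)$"
)
_SNV_RE = re.compile(r"^(?P<pos>-?\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT]):(?P<ann>\w+)$")


def isomir_name(call: IsomirCall) -> str:
    """Deterministic, parseable nomenclature string.

    Grammar: ``<mature>|5p<o5>|3p<o3>|nta:<seq|->|snv:<pos><ref>><alt>:<ann>[,..]|-``
    Injective over distinct (mature, offset5, offset3, nta, snvs) tuples.
    """
    nta = call.nta_seq if call.nta_seq else "-"
    if call.snvs:
        parts = ",".join(
            f"{s.pos_on_mature}{s.ref}>{s.alt}:{s.annotation}"
            for s in sorted(call.snvs, key=lambda s: s.pos_on_mature)
        )
        snvs = f"snv:{parts}"
    else:
        snvs = "-"
    return f"{call.mature_name}|5p{call.offset5}|3p{call.offset3}|nta:{nta}|{snvs}"


def parse_isomir_name(name: str):
    m = _NAME_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable isomiR name: {name!r}")
    o5, o3 = int(m["o5"]), int(m["o3"])
    nta = "" if m["nta"] == "-" else m["nta"]
    snvs: list[SNV] = []
    if m["snvs"] != "-":
        for tok in m["snvs"][4:].split(","):
            sm = _SNV_RE.match(tok)
            if sm is None:
                raise ValueError(f"unparseable SNV token {tok!r} in {name!r}")
            snvs.append(
                SNV(
                    pos_on_mature=int(sm["pos"]),
                    ref=sm["ref"],
                    alt=sm["alt"],
                    annotation=sm["ann"],
                )
            )
    return m["mature"], o5, o3, nta, tuple(snvs)


def call_from_name(name: str, aligned_len: int = 0, count: int = 1) -> IsomirCall:
    """Reconstruct an IsomirCall from its nomenclature string."""
    mature, o5, o3, nta, snvs = parse_isomir_name(name)
    return IsomirCall(
        mature_name=mature,
        offset5=o5,
        offset3=o3,
        templated3=not nta,
        nta_seq=nta,
        snvs=snvs,
        aligned_len=aligned_len,
        count=count,
    )


# ---------------------------------------------------------------------------
# driver


@dataclass
class CallStats:
    n_reads: int = 0
    n_unplaced: int = 0
    n_unassigned: int = 0
    n_discarded_terminal: int = 0
    n_called: int = 0


def call_reads(
    reads: Iterable[tuple[str, int]],
    bundle: ReferenceBundle,
    config: PlacementConfig | None = None,
    apply_terminal_filter: bool = True,
) -> tuple[list[IsomirCall], CallStats]:
    """Place, call, annotate and filter a collection of (sequence, count)
    reads against a reference bundle. Identical annotations are aggregated
    by summed count."""
    cfg = config or PlacementConfig()
    matures = list(bundle.matures.values())
    stats = CallStats()
    agg: dict[str, IsomirCall] = {}
    for seq, count in reads:
        stats.n_reads += count
        placement = place_read(seq, bundle.hairpins, cfg)
        if placement is None:
            stats.n_unplaced += count
            continue
        call = call_isomir(placement, matures, bundle.hairpins)
        if call is None:
            stats.n_unassigned += count
            continue
        call = annotate_variants(call, bundle.variants)
        key = call.name
        if key in agg:
            agg[key] = replace(agg[key], count=agg[key].count + count)
        else:
            agg[key] = replace(call, count=count)

    calls = list(agg.values())
    if apply_terminal_filter:
        calls, discarded = filter_terminal_unannotated(calls)
        stats.n_discarded_terminal = sum(c.count for c in discarded)
    stats.n_called = sum(c.count for c in calls)
    return calls, stats
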
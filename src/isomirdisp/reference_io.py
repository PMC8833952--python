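"""Reference bundle, annotation-table and sample-sheet I/O.

The reference bundle consists of hairpin sequences (FASTA), mature-miRNA
coordinates on those hairpins (TSV, 0-based half-open), and a variant
annotation table (TSV, 1-based positions on the mature). All coordinates are
held 0-based half-open internally; genomic coordinates are 1-based inclusive
on both ends. Sequences are normalized to the DNA alphabet (U -> T) on
ingest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Hairpin",
    "MatureAnnotation",
    "VariantRecord",
    "Sample",
    "SampleSheet",
    "ReferenceBundle",
    "read_reference_bundle",
    "write_reference_bundle",
    "read_sample_sheet",
    "write_isomir_gff",
    "read_isomir_gff",
]

_DNA = set("ACGT")
VARIANT_CLASSES = ("EDITING", "SNP", "SOMATIC")
RACES = ("W", "BAA")
TISSUES = ("TUMOR", "NORMAL")

# seed = mature positions 2..7, 1-based inclusive
SEED_START = 2
SEED_END = 7


def _normalize_seq(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _DNA
    if bad:
        raise ValueError(f"invalid bases {sorted(bad)} in sequence")
    return s


@dataclass(frozen=True)
class Hairpin:
    """A miRNA precursor sequence with its genomic footprint."""

    id: str
    sequence: str
    chrom: str = "chrUn"
    genome_start: int = 1  # 1-based inclusive
    genome_end: int = 0  # 1-based inclusive; 0 => derive from length
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize_seq(self.sequence))
        if not self.sequence:
            raise ValueError(f"hairpin {self.id}: empty sequence")
        if self.genome_end == 0:
            object.__setattr__(
                self, "genome_end", self.genome_start + len(self.sequence) - 1
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"hairpin {self.id}: bad strand {self.strand!r}")
        if self.genome_end - self.genome_start + 1 != len(self.sequence):
            raise ValueError(
                f"hairpin {self.id}: genomic span "
                f"{self.chrom}:{self.genome_start}-{self.genome_end} does not "
                f"match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """Mature miRNA location on its hairpin, 0-based half-open."""

    name: str
    hairpin_id: str
    start: int
    end: int
    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"mature {self.name}: arm must be 5p/3p, got {self.arm!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"mature {self.name}: bad interval [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def sequence(self, hairpin: Hairpin) -> str:
        return hairpin.sequence[self.start : self.end]


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant position on a mature miRNA (1-based)."""

    mature_name: str
    pos_on_mature: int
    ref: str
    alt: str
    var_class: str

    def __post_init__(self) -> None:
        if self.var_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if self.ref not in _DNA or self.alt not in _DNA:
            raise ValueError(f"bad ref/alt {self.ref!r}>{self.alt!r}")
        if self.var_class == "EDITING" and (self.ref, self.alt) != ("A", "G"):
            raise ValueError(
                f"EDITING record at {self.mature_name}:{self.pos_on_mature} must be "
                f"A>G, got {self.ref}>{self.alt}"
            )
        if self.pos_on_mature < 1:
            raise ValueError("pos_on_mature is 1-based, must be >= 1")


@dataclass(frozen=True)
class ReferenceBundle:
    hairpins: Mapping[str, Hairpin]
    matures: Mapping[str, MatureAnnotation]
    variants: tuple[VariantRecord, ...]

    def matures_of(self, hairpin_id: str) -> list[MatureAnnotation]:
        return [m for m in self.matures.values() if m.hairpin_id == hairpin_id]

    def variants_of(self, mature_name: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.mature_name == mature_name]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    race: str
    tissue: str
    os_time: float | None = None
    os_event: int | None = None
    rfs_time: float | None = None
    rfs_event: int | None = None

    def __post_init__(self) -> None:
        if self.race not in RACES:
            raise ValueError(f"sample {self.sample_id}: unknown race {self.race!r}")
        if self.tissue not in TISSUES:
            raise ValueError(f"sample {self.sample_id}: unknown tissue {self.tissue!r}")
        for t, e, label in (
            (self.os_time, self.os_event, "os"),
            (self.rfs_time, self.rfs_event, "rfs"),
        ):
            if t is not None and t < 0:
                raise ValueError(f"sample {self.sample_id}: negative {label}_time")
            if e is not None and e not in (0, 1):
                raise ValueError(f"sample {self.sample_id}: {label}_event must be 0/1")

    @property
    def group(self) -> str:
        return f"{self.race}_{'T' if self.tissue == 'TUMOR' else 'N'}"

    def has_survival(self, event_type: str = "os") -> bool:
        t, e = (
            (self.os_time, self.os_event)
            if event_type == "os"
            else (self.rfs_time, self.rfs_event)
        )
        return t is not None and e is not None


@dataclass
class SampleSheet:
    samples: dict[str, Sample] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples.values())

    def __getitem__(self, sample_id: str) -> Sample:
        return self.samples[sample_id]

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s in self:
            out.setdefault(s.group, []).append(s.sample_id)
        return out

    def survival_samples(self, event_type: str = "os") -> list[Sample]:
        return [s for s in self if s.has_survival(event_type)]


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path) -> list[dict[str, str]]:
    with open(path, newline="") as fh:
        rows = [
            row
            for row in csv.DictReader(
                (ln for ln in fh if not ln.startswith("#")), delimiter="\t"
            )
        ]
    return rows


def read_reference_bundle(
    hairpin_fasta: str | Path,
    mature_table: str | Path,
    variant_table: str | Path | None = None,
) -> ReferenceBundle:
    """Load and cross-validate hairpins, matures and variant annotations.

    Raises ``ValueError`` naming the offending row on any dangling id or
    out-of-range coordinate.
    """
    hairpins: dict[str, Hairpin] = {}
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        desc = rec.description.split()
        chrom, start, end, strand = "chrUn", 1, 0, "+"
        for tok in desc[1:]:
            if tok.startswith("loc="):
                chrom, span, strand = tok[4:].split(":")
                lo, hi = span.split("-")
                start, end = int(lo), int(hi)
        if rec.id in hairpins:
            raise ValueError(f"duplicate hairpin id {rec.id}")
        hairpins[rec.id] = Hairpin(
            id=rec.id,
            sequence=str(rec.seq),
            chrom=chrom,
            genome_start=start,
            genome_end=end,
            strand=strand,
        )

    matures: dict[str, MatureAnnotation] = {}
    for i, row in enumerate(_read_tsv(mature_table), start=2):
        m = MatureAnnotation(
            name=row["name"],
            hairpin_id=row["hairpin_id"],
            start=int(row["start"]),
            end=int(row["end"]),
            arm=row["arm"],
        )
        if m.hairpin_id not in hairpins:
            raise ValueError(
                f"{mature_table} line {i}: mature {m.name} references unknown "
                f"hairpin {m.hairpin_id!r}"
            )
        if m.end > len(hairpins[m.hairpin_id]):
            raise ValueError(
                f"{mature_table} line {i}: mature {m.name} end {m.end} exceeds "
                f"hairpin {m.hairpin_id} length {len(hairpins[m.hairpin_id])}"
            )
        if m.name in matures:
            raise ValueError(f"duplicate mature name {m.name}")
        matures[m.name] = m

    variants: list[VariantRecord] = []
    if variant_table is not None:
        for i, row in enumerate(_read_tsv(variant_table), start=2):
            v = VariantRecord(
                mature_name=row["mature_name"],
                pos_on_mature=int(row["pos_on_mature"]),
                ref=_normalize_seq(row["ref"]),
                alt=_normalize_seq(row["alt"]),
                var_class=row["class"],
            )
            if v.mature_name not in matures:
                raise ValueError(
                    f"{variant_table} line {i}: variant references unknown mature "
                    f"{v.mature_name!r}"
                )
            if v.pos_on_mature > len(matures[v.mature_name]):
                raise ValueError(
                    f"{variant_table} line {i}: position {v.pos_on_mature} outside "
                    f"mature {v.mature_name} of length {len(matures[v.mature_name])}"
                )
            variants.append(v)

    return ReferenceBundle(hairpins=hairpins, matures=matures, variants=tuple(variants))


def write_reference_bundle(
    bundle: ReferenceBundle,
    hairpin_fasta: str | Path,
    mature_table: str | Path,
    variant_table: str | Path,
) -> None:
    records = [
        SeqRecord(
            Seq(h.sequence),
            id=h.id,
            description=f"loc={h.chrom}:{h.genome_start}-{h.genome_end}:{h.strand}",
        )
        for h in bundle.hairpins.values()
    ]
    SeqIO.write(records, str(hairpin_fasta), "fasta")

    with open(mature_table, "w", newline="") as fh:
        fh.write("# coordinates on hairpin, 0-based half-open\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "hairpin_id", "start", "end", "arm"])
        for m in bundle.matures.values():
            w.writerow([m.name, m.hairpin_id, m.start, m.end, m.arm])

    with open(variant_table, "w", newline="") as fh:
        fh.write("# positions on mature, 1-based\n")
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["mature_name", "pos_on_mature", "ref", "alt", "class"])
        for v in bundle.variants:
            w.writerow([v.mature_name, v.pos_on_mature, v.ref, v.alt, v.var_class])


def _opt_float(x: str) -> float | None:
    x = x.strip()
    return None if x in ("", "NA", "NaN", ".") else float(x)


def _opt_int(x: str) -> int | None:
    x = x.strip()
    return None if x in ("", "NA", "NaN", ".") else int(x)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet.

    Required columns: sample_id, race, tissue. Optional survival columns
    (os_time, os_event, rfs_time, rfs_event) may be empty or 'NA'; samples
    with missing survival fields remain usable for expression analyses.
    """
    sheet = SampleSheet()
    for i, row in enumerate(_read_tsv(path), start=2):
        s = Sample(
            sample_id=row["sample_id"],
            race=row["race"],
            tissue=row["tissue"],
            os_time=_opt_float(row.get("os_time", "")),
            os_event=_opt_int(row.get("os_event", "")),
            rfs_time=_opt_float(row.get("rfs_time", "")),
            rfs_event=_opt_int(row.get("rfs_event", "")),
        )
        if s.sample_id in sheet.samples:
            raise ValueError(f"{path} line {i}: duplicate sample id {s.sample_id}")
        sheet.samples[s.sample_id] = s
    return sheet


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    def fmt(x) -> str:
        return "" if x is None else (f"{x:g}" if isinstance(x, float) else str(x))

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["sample_id", "race", "tissue", "os_time", "os_event", "rfs_time", "rfs_event"]
        )
        for s in sheet:
            w.writerow(
                [
                    s.sample_id,
                    s.race,
                    s.tissue,
                    fmt(s.os_time),
                    fmt(s.os_event),
                    fmt(s.rfs_time),
                    fmt(s.rfs_event),
                ]
            )


# --- isomiR GFF3-dialect output -------------------------------------------

_GFF_HEADER = "##gff-version 3"


def write_isomir_gff(calls: Iterable, path: str | Path) -> None:
    """Write isomiR calls as 9-column GFF3-dialect records.

    The deterministic nomenclature string is stored under ``Name=``; the
    aligned length under ``alen=`` so a matching reader round-trips the call
    set losslessly.
    """
    with open(path, "w") as fh:
        fh.write(_GFF_HEADER + "\n")
        for c in calls:
            attrs = f"Name={c.name};alen={c.aligned_len}"
            start = 1
            end = c.aligned_len + len(c.nta_seq)
            fh.write(
                "\t".join(
                    [
                        c.mature_name,
                        "isomirdisp",
                        "isomiR",
                        str(start),
                        str(end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_isomir_gff(path: str | Path) -> list:
    from .isomir_caller import call_from_name

    calls = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            cols = ln.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF line: {ln!r}")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            calls.append(call_from_name(attrs["Name"], aligned_len=int(attrs["alen"])))
    return calls
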
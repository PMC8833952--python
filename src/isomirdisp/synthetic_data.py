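"""Seed-deterministic generators with planted ground truth: reference
bundles, small-RNA reads with known isoform events, four-group count
matrices with known trends, and proportional-hazards survival cohorts.

Every generator emits a machine-readable truth table alongside the data so
the pipeline's output can be checked against the planted labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .isomir_caller import SNV, IsomirCall, isomir_name
from .quantify import CountMatrix, GROUPS
from .reference_io import (
    Hairpin,
    MatureAnnotation,
    ReferenceBundle,
    SEED_END,
    SEED_START,
    VariantRecord,
)
from .survival_signature import SurvivalRecord

__all__ = [
    "SimConfig",
    "make_reference",
    "simulate_reads",
    "write_reads_fastq",
    "simulate_count_matrix",
    "simulate_survival",
]

_BASES = np.array(list("ACGT"))

READ_CATEGORIES = ("canonical", "shift5", "shift3", "shift53", "nta", "edit")


@dataclass
class SimConfig:
    seed: int = 0
    # reference
    n_hairpins: int = 10
    hairpin_len: tuple[int, int] = (60, 90)
    mature_len: tuple[int, int] = (20, 23)
    # reads
    read_depth: int = 1000
    fractions: dict = dc_field(
        default_factory=lambda: {
            "shift5": 0.1,
            "shift3": 0.2,
            "shift53": 0.1,
            "nta": 0.15,
            "edit": 0.15,
        }
    )
    editing_rate: float = 1.0
    # count matrices
    nb_mean: float = 100.0
    nb_dispersion: float = 0.1
    group_sizes: tuple[int, int, int, int] = (15, 15, 15, 15)
    effect_size: float = 2.0
    n_null_rows: int = 100
    trend_rows: dict = dc_field(default_factory=dict)  # trend label -> n rows
    # survival
    n_patients: int = 200
    censoring_rate: float = 0.3
    baseline_hazard: float = 1e-3

    def __post_init__(self) -> None:
        extra = set(self.fractions) - set(READ_CATEGORIES)
        if extra:
            raise ValueError(f"unknown read categories: {sorted(extra)}")
        if sum(self.fractions.values()) > 1 + 1e-9:
            raise ValueError("read-category fractions must sum to <= 1")
        if not (0 <= self.editing_rate <= 1 and 0 <= self.censoring_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# reference

_MARGIN5 = 5  # hairpin bases upstream of the mature
_MARGIN3 = 7  # downstream, leaving room for templated 3' extensions


def make_reference(cfg: SimConfig, max_tries: int = 200) -> ReferenceBundle:
    """Random hairpins, one mature each, every seed-region A registered as
    an editing site. Mature sequences are rejection-sampled to occur exactly
    once across the whole hairpin set so placement is unambiguous."""
    rng = np.random.default_rng(cfg.seed)
    hairpins: dict[str, Hairpin] = {}
    matures: dict[str, MatureAnnotation] = {}
    variants: list[VariantRecord] = []
    genome_cursor = 1_000_000

    for i in range(cfg.n_hairpins):
        for attempt in range(max_tries):
            hp_len = int(rng.integers(cfg.hairpin_len[0], cfg.hairpin_len[1] + 1))
            mat_len = int(rng.integers(cfg.mature_len[0], cfg.mature_len[1] + 1))
            if hp_len - mat_len < _MARGIN5 + _MARGIN3:
                continue
            seq = list(rng.choice(_BASES, size=hp_len))
            start = int(rng.integers(_MARGIN5, hp_len - mat_len - _MARGIN3 + 1))
            # guarantee at least one A in the seed (mature pos 2..7)
            seed_idx = [start + p - 1 for p in range(SEED_START, SEED_END + 1)]
            if not any(seq[k] == "A" for k in seed_idx):
                seq[int(rng.choice(seed_idx))] = "A"
            seq_s = "".join(seq)
            mature_seq = seq_s[start : start + mat_len]
            occurrences = sum(h.sequence.count(mature_seq) for h in hairpins.values())
            occurrences += seq_s.count(mature_seq)
            if occurrences == 1 and not any(
                m_seq in seq_s
                for m_seq in (
                    matures[m].sequence(hairpins[matures[m].hairpin_id])
                    for m in matures
                )
            ):
                break
        else:
            raise RuntimeError("could not build a unique reference; relax config")

        hid = f"hp-{i + 1:03d}"
        arm = "5p" if start + mat_len / 2 < hp_len / 2 else "3p"
        mname = f"miR-{i + 1:03d}-{arm}"
        hairpins[hid] = Hairpin(
            id=hid,
            sequence=seq_s,
            chrom="chrS",
            genome_start=genome_cursor,
            genome_end=genome_cursor + hp_len - 1,
        )
        genome_cursor += hp_len + 100
        matures[mname] = MatureAnnotation(
            name=mname, hairpin_id=hid, start=start, end=start + mat_len, arm=arm
        )
        for p in range(SEED_START, SEED_END + 1):
            if mature_seq[p - 1] == "A":
                variants.append(
                    VariantRecord(
                        mature_name=mname,
                        pos_on_mature=p,
                        ref="A",
                        alt="G",
                        var_class="EDITING",
                    )
                )

    return ReferenceBundle(
        hairpins=hairpins, matures=matures, variants=tuple(variants)
    )


# ---------------------------------------------------------------------------
# reads


def _other_base(rng: np.random.Generator, templated: str) -> str:
    """A 3' NTA base from {A, T} guaranteed to differ from the hairpin
    continuation, so the caller cannot re-template it."""
    if templated == "A":
        return "T"
    if templated == "T":
        return "A"
    return str(rng.choice(["A", "T"]))


def simulate_reads(
    reference: ReferenceBundle, cfg: SimConfig
) -> pd.DataFrame:
    """Reads with planted isoform events.

    Returns a DataFrame with one row per read: read_id, seq, and the truth
    columns (mature, category, offset5, offset3, nta_seq, snvs, name) where
    `name` is the nomenclature string the caller should reproduce.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    mature_names = sorted(reference.matures)
    cats = list(cfg.fractions)
    probs = list(cfg.fractions.values())
    cats.append("canonical")
    probs.append(max(0.0, 1.0 - sum(probs)))

    edit_sites = {
        m: [v.pos_on_mature for v in reference.variants_of(m) if v.var_class == "EDITING"]
        for m in mature_names
    }

    rows = []
    for ridx in range(cfg.read_depth):
        mname = mature_names[int(rng.integers(len(mature_names)))]
        mat = reference.matures[mname]
        hp = reference.hairpins[mat.hairpin_id].sequence
        category = str(rng.choice(cats, p=np.asarray(probs) / sum(probs)))

        o5 = t3 = 0
        nta = ""
        snvs: list[SNV] = []
        if category in ("shift5", "shift53"):
            o5 = int(rng.choice([-2, -1, 1, 2]))
        if category in ("shift3", "shift53"):
            t3 = int(rng.choice([-2, -1, 1, 2]))
        if category == "nta":
            n_nta = int(rng.integers(1, 3))
            pos = mat.end
            for _ in range(n_nta):
                cont = hp[pos] if pos < len(hp) else ""
                nta += _other_base(rng, cont)
                pos += 1
        if category == "edit":
            if edit_sites[mname] and rng.random() < cfg.editing_rate:
                p = int(rng.choice(edit_sites[mname]))
                snvs.append(SNV(pos_on_mature=p, ref="A", alt="G", annotation="EDITING"))
            else:
                category = "canonical"

        core = list(hp[mat.start + o5 : mat.end + t3])
        for s in snvs:
            core[s.pos_on_mature - 1 - o5] = s.alt
        seq = "".join(core) + nta

        call = IsomirCall(
            mature_name=mname,
            offset5=o5,
            offset3=t3 + len(nta),
            templated3=not nta,
            nta_seq=nta,
            snvs=tuple(snvs),
            aligned_len=len(core),
        )
        rows.append(
            {
                "read_id": f"read-{ridx + 1:06d}",
                "seq": seq,
                "mature": mname,
                "category": category,
                "offset5": o5,
                "offset3": t3 + len(nta),
                "nta_seq": nta,
                "snvs": ";".join(
                    f"{s.pos_on_mature}{s.ref}>{s.alt}" for s in snvs
                ),
                "name": isomir_name(call),
            }
        )
    return pd.DataFrame(rows)


def write_reads_fastq(reads: pd.DataFrame, path: str | Path) -> None:
    """Constant-quality FASTQ (the caller ignores qualities)."""
    with open(path, "w") as fh:
        for _, r in reads.iterrows():
            fh.write(f"@{r['read_id']}\n{r['seq']}\n+\n{'I' * len(r['seq'])}\n")


def write_truth_table(reads: pd.DataFrame, path: str | Path) -> None:
    reads.drop(columns=["seq"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices

_TREND_MEANS = {
    # multipliers (WN, WT, BN, BT) at effect size e
    "MONOTONIC_INC": lambda e: (1.0, e, e**2, e**3),
    "MONOTONIC_DEC": lambda e: (e**3, e**2, e, 1.0),
    "UP_BOTH": lambda e: (1.0, e, 1.0, e),
    "DOWN_BOTH": lambda e: (e, 1.0, e, 1.0),
    "UP_W_DOWN_BAA": lambda e: (1.0, e, e, 1.0),
    "DOWN_W_UP_BAA": lambda e: (e, 1.0, 1.0, e),
}


def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float, size: int
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_count_matrix(
    cfg: SimConfig,
) -> tuple[CountMatrix, dict[str, str], pd.DataFrame]:
    """Four-group NB count matrix with planted trend rows.

    Returns (matrix, design, truth) where truth has one row per feature with
    its planted trend label ('NULL' for no effect) and effect size. Effect
    size 1.0 collapses every planted trend to null and is labeled as such.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    e = cfg.effect_size
    sizes = cfg.group_sizes
    if any(n <= 0 for n in sizes):
        raise ValueError("group sizes must be positive")
    samples = []
    design: dict[str, str] = {}
    for g, n in zip(GROUPS, sizes):
        for k in range(n):
            sid = f"{g}_{k + 1:02d}"
            samples.append(sid)
            design[sid] = g

    rows, truth_rows, data = [], [], []

    def add_row(rid: str, mults, label: str, eff: float) -> None:
        counts = np.concatenate(
            [
                _nb_draw(rng, cfg.nb_mean * mult, cfg.nb_dispersion, n)
                for mult, n in zip(mults, sizes)
            ]
        )
        rows.append(rid)
        data.append(counts)
        truth_rows.append((rid, label, eff))

    idx = 0
    for trend, n_rows in cfg.trend_rows.items():
        if trend not in _TREND_MEANS:
            raise ValueError(f"unknown trend {trend!r}")
        for _ in range(n_rows):
            idx += 1
            label = trend if e != 1.0 else "NULL"
            add_row(f"iso-{idx:05d}", _TREND_MEANS[trend](e), label, e)
    for _ in range(cfg.n_null_rows):
        idx += 1
        add_row(f"iso-{idx:05d}", (1.0, 1.0, 1.0, 1.0), "NULL", 1.0)

    counts = pd.DataFrame(np.vstack(data), index=rows, columns=samples, dtype=int)
    truth = pd.DataFrame(truth_rows, columns=["feature", "trend", "effect_size"])
    return CountMatrix(counts), design, truth


# ---------------------------------------------------------------------------
# survival


def _calibrate_uniform_censoring(times: np.ndarray, rate: float) -> float:
    """c_max such that mean_i P(U(0, c_max) < T_i) == rate (bisection).

    P(C < T_i) = min(T_i, c) / c is decreasing in c, from 1 to 0, so a root
    exists for any rate in (0, 1).
    """
    if not (0 < rate < 1):
        raise ValueError("rate must lie in (0, 1) for calibration")

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(times, c)) / c)

    lo, hi = float(times.min()) * 1e-6, float(times.max()) * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > rate:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def simulate_survival(
    cfg: SimConfig,
    n_features: int,
    prognostic_betas: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, list[SurvivalRecord], pd.DataFrame]:
    """Proportional-hazards cohort with a known prognostic feature subset.

    Expression is standard-normal on the log scale (i.e. raw abundance is
    log-normal; the matrix returned is the normalized log-expression the
    downstream workflow consumes). Event times are exponential with hazard
    h0 * exp(sum beta_f * x_f). Censoring times are independent
    Uniform(0, c_max), with c_max calibrated by bisection so the expected
    censored fraction equals `censoring_rate`; records are right-censored at
    min(T, C).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    feats = [f"feat-{i + 1:04d}" for i in range(n_features)]
    betas = dict(prognostic_betas or {})
    unknown = set(betas) - set(feats)
    if unknown:
        raise ValueError(f"prognostic features not among generated ones: {sorted(unknown)}")

    X = rng.standard_normal((cfg.n_patients, n_features))
    expr = pd.DataFrame(
        X, index=[f"pt-{i + 1:04d}" for i in range(cfg.n_patients)], columns=feats
    )
    lp = np.zeros(cfg.n_patients)
    for f, b in betas.items():
        lp += b * expr[f].values

    times = rng.exponential(1.0 / (cfg.baseline_hazard * np.exp(lp)))
    if cfg.censoring_rate <= 0:
        obs, events = times, np.ones(cfg.n_patients, dtype=int)
    else:
        c_max = _calibrate_uniform_censoring(times, cfg.censoring_rate)
        cens = rng.uniform(0, c_max, size=cfg.n_patients)
        events = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    records = [
        SurvivalRecord(sample_id=pid, time=float(t), event=int(e))
        for pid, t, e in zip(expr.index, obs, events)
    ]
    truth = pd.DataFrame(
        {"feature": feats, "beta": [betas.get(f, 0.0) for f in feats]}
    )
    return expr, records, truth
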
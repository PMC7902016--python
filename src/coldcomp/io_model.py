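"""Domain types and readers/writers for the pipeline's external formats.

Covers protein/CDS FASTA input (with standard-code translation and the
``>=150 nt`` length screen applied to predicted coding sequences),
annotation tables keyed by the cellular-function and subcellular-location
group codes, dipeptide Tm-weight tables, growth-curve CSV files, and the
study-wide configuration object.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger("coldcomp")

#: The 20 standard amino-acid one-letter codes, alphabetical.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA_ALPHABET)
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}

#: All 400 ordered dipeptides over the standard alphabet.
DIPEPTIDES: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(AA_ALPHABET, repeat=2)
)

#: Cellular-function group codes (26).
FUNCTION_CODES = frozenset(
    {
        "AARE", "CAPR", "CHFC", "CYPR", "DRPR", "DRRP", "ENZY", "EXOS",
        "GLYC", "LIBP", "MERB", "METR", "MIBI", "PEPT", "PPAP", "PREN",
        "PRKI", "PROT", "RIBI", "RIBO", "SPLI", "TLFA", "TNFA", "TRBI",
        "TRMA", "UBSY",
    }
)

#: Subcellular-localization group codes (9).
LOCALIZATION_CODES = frozenset(
    {"CEME", "CYTO", "ENRE", "EXTR", "GOAP", "LYVA", "MITO", "NUCL", "PERO"}
)

#: Reserved code for the whole annotated proteome of an organism.
ALL_CODE = "ALL"

VALID_CODES = FUNCTION_CODES | LOCALIZATION_CODES | {ALL_CODE}


class InputError(ValueError):
    """Malformed or invalid external input."""


class CdsRejected(ValueError):
    """A coding sequence failed the translation screen."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    """A translated, annotated-ready protein sequence.

    ``sequence`` is restricted to the 20 standard amino-acid letters;
    records violating this are rejected at read time, not stored.
    """

    protein_id: str
    organism_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - AA_SET
        if bad:
            raise InputError(
                f"{self.protein_id}: non-standard letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationRecord:
    """Annotation of one protein: free-text label plus group codes."""

    protein_id: str
    label: str
    function_codes: frozenset[str] = frozenset()
    localization_code: str | None = None

    def __post_init__(self):
        bad = set(self.function_codes) - (FUNCTION_CODES | {ALL_CODE})
        if bad:
            raise InputError(f"{self.protein_id}: unknown function codes {sorted(bad)}")
        if self.localization_code is not None and self.localization_code not in (
            LOCALIZATION_CODES | {ALL_CODE}
        ):
            raise InputError(
                f"{self.protein_id}: unknown localization code {self.localization_code!r}"
            )

    @property
    def group_codes(self) -> frozenset[str]:
        codes = set(self.function_codes)
        if self.localization_code:
            codes.add(self.localization_code)
        return frozenset(codes)


@dataclass(frozen=True)
class FlexibilityScheme:
    """Partition of the amino-acid alphabet by side-chain flexibility.

    Defaults follow the flexibility-index classification used for
    cold-adaptation composition analyses: very flexible E, G, K, N, Q, S;
    moderately flexible A, D, H, I, P, R, T, V; the remaining six letters
    (C, F, L, M, W, Y) are treated as rigid.
    """

    very_flexible: frozenset[str] = frozenset("EGKNQS")
    moderately_flexible: frozenset[str] = frozenset("ADHIPRTV")
    rigid: frozenset[str] = frozenset("CFLMWY")

    def __post_init__(self):
        sets = (self.very_flexible, self.moderately_flexible, self.rigid)
        union = frozenset().union(*sets)
        if union != AA_SET or sum(map(len, sets)) != 20:
            raise InputError("flexibility classes must partition the 20-letter alphabet")


@dataclass(frozen=True)
class TmWeightTable:
    """Per-dipeptide Tm weights with a three-way category rule.

    A dipeptide is *negative* if its weight is < 0, *low* if
    ``0 <= weight < low_threshold``, and *other* otherwise.  Low and
    negative weights mark dipeptides whose presence is associated with a
    lower protein melting temperature.
    """

    weight: Mapping[str, float]
    low_threshold: float

    def __post_init__(self):
        keys = set(self.weight)
        if keys != set(DIPEPTIDES):
            missing = sorted(set(DIPEPTIDES) - keys)
            extra = sorted(keys - set(DIPEPTIDES))
            raise InputError(
                f"Tm table must have exactly the 400 dipeptides; "
                f"missing={missing[:5]}{'...' if len(missing) > 5 else ''} "
                f"extra={extra[:5]}{'...' if len(extra) > 5 else ''}"
            )

    def category(self, dipeptide: str) -> str:
        w = self.weight[dipeptide]
        if w < 0:
            return "negative"
        if w < self.low_threshold:
            return "low"
        return "other"

    def category_matrix(self) -> np.ndarray:
        """20x20 int8 matrix: 0=negative, 1=low, 2=other, indexed [first, second]."""
        m = np.empty((20, 20), dtype=np.int8)
        for d in DIPEPTIDES:
            c = self.category(d)
            m[AA_INDEX[d[0]], AA_INDEX[d[1]]] = 0 if c == "negative" else (1 if c == "low" else 2)
        return m


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD600 time series at a single cultivation temperature."""

    organism_id: str
    temperature: float
    replicate: int
    times: tuple[float, ...]
    od: tuple[float, ...]

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if t.size < 4:
            raise InputError(f"{self.organism_id}@{self.temperature}: need >=4 time points")
        if t.size != od.size:
            raise InputError("times and od lengths differ")
        if not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if np.any(od < 0):
            raise InputError("OD values must be >= 0")


@dataclass
class StudyConfig:
    """Study-wide thresholds and strata.

    alpha            significance level for the Tukey screen and tie tests
    r2_report        minimum R^2 for a regression to be reported
    r2_highlight     minimum R^2 for a reported regression to be highlighted
    min_points       minimum difference points required to fit a regression
    min_cds_nt       minimum predicted CDS length (nt) admitted to translation
    gr_stratum_cut   growth-rate cut (h^-1) splitting fast/slow strata
    otg_strata       inclusive OTG intervals (degC) defining OTG strata
    temp_bins        named inclusive growth-temperature bins (degC)
    min_label_presence  minimum organisms sharing a label for label analysis
    """

    alpha: float = 0.05
    r2_report: float = 0.5
    r2_highlight: float = 0.7
    min_points: int = 3
    min_cds_nt: int = 150
    gr_stratum_cut: float = 1.0
    otg_strata: list[tuple[float, float]] = field(
        default_factory=lambda: [(10.0, 15.0), (19.0, 22.0)]
    )
    temp_bins: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "T10-22": (10.0, 22.0),
            "T23-28": (23.0, 28.0),
            "T30-37": (30.0, 37.0),
        }
    )
    min_label_presence: int = 3
    require_omnibus: bool = False
    use_display_otg: bool = True
    tie_method: str = "tukey"
    fit_r2_gate: float = 0.98
    min_window: int = 8
    range_fraction: float = 0.4
    od_floor: float = 0.05
    saturation_correction: bool = True

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise InputError("alpha must be in (0, 1)")
        if not 0 < self.r2_report <= self.r2_highlight <= 1:
            raise InputError("require 0 < r2_report <= r2_highlight <= 1")
        if self.min_points < 2:
            raise InputError("min_points must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "otg_strata" in raw:
            raw["otg_strata"] = [tuple(map(float, iv)) for iv in raw["otg_strata"]]
        if "temp_bins" in raw:
            raw["temp_bins"] = {k: tuple(map(float, v)) for k, v in raw["temp_bins"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            f.name: getattr(self, f.name) for f in fields(self)
        }
        d["otg_strata"] = [list(iv) for iv in d["otg_strata"]]
        d["temp_bins"] = {k: list(v) for k, v in d["temp_bins"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@dataclass
class FastaReadResult:
    records: list[ProteinRecord]
    n_dropped: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def read_protein_fasta(path: str | Path, organism_id: str) -> FastaReadResult:
    """Read a protein FASTA; drop (and count) records with non-standard letters.

    Sequences are upper-cased.  Letters outside the 20-letter alphabet
    (B, J, O, U, X, Z, ``*`` ...) reject the whole record, since composition
    percentages must be taken over a fixed alphabet.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    kept: list[ProteinRecord] = []
    dropped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq or set(seq) - AA_SET:
            dropped += 1
            continue
        kept.append(ProteinRecord(rec.id, organism_id, seq))
    if not kept and dropped == 0:
        raise InputError(f"empty FASTA: {path}")
    if dropped:
        logger.warning("%s: dropped %d record(s) with non-standard letters", path, dropped)
    return FastaReadResult(kept, dropped)


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.protein_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# CDS translation
# ---------------------------------------------------------------------------

_NT_SET = frozenset("ACGT")


def translate_cds(nucleotide_sequence: str, min_cds_nt: int = 150) -> str:
    """Translate a predicted CDS under the standard code.

    Applies the screening rules used for predicted coding sequences:
    sequences shorter than ``min_cds_nt`` nucleotides, sequences with
    ambiguous (non-ACGT) bases, out-of-frame lengths, or internal stop
    codons are rejected (:class:`CdsRejected` with a reason).  A single
    terminal stop codon is trimmed and excluded from the product.
    """
    nt = nucleotide_sequence.upper()
    if len(nt) < min_cds_nt:
        raise CdsRejected("short", f"{len(nt)} nt < {min_cds_nt}")
    bad = set(nt) - _NT_SET
    if bad:
        raise CdsRejected("ambiguous", f"non-ACGT bases {sorted(bad)}")
    if len(nt) % 3 != 0:
        raise CdsRejected("frame", f"length {len(nt)} not a multiple of 3")
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise CdsRejected("internal_stop", f"stop at codon {aa.index('*') + 1}")
    if not aa:
        raise CdsRejected("empty", "no residues after trimming terminal stop")
    return aa


def translate_cds_fasta(
    path: str | Path, organism_id: str, min_cds_nt: int = 150
) -> tuple[list[ProteinRecord], dict[str, int]]:
    """Translate every CDS in a nucleotide FASTA; return records + rejection tally."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records: list[ProteinRecord] = []
    rejected: dict[str, int] = {}
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        try:
            aa = translate_cds(str(rec.seq), min_cds_nt)
        except CdsRejected as e:
            rejected[e.reason] = rejected.get(e.reason, 0) + 1
            continue
        records.append(ProteinRecord(rec.id, organism_id, aa))
    if n == 0:
        raise InputError(f"empty FASTA: {path}")
    if rejected:
        logger.warning("%s: rejected CDSs by reason: %s", path, rejected)
    return records, rejected


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANN_COLS = ["protein_id", "label", "function_codes", "localization_code"]


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read a TSV of protein annotations (label, function codes, localization).

    Function codes are semicolon-separated; localization may be empty.
    Unknown codes raise, naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANN_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    out: list[AnnotationRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        fcodes = frozenset(c for c in str(row.function_codes).split(";") if c)
        loc = str(row.localization_code) or None
        try:
            out.append(AnnotationRecord(row.protein_id, row.label, fcodes, loc))
        except InputError as e:
            raise InputError(f"{path} row {i + 2}: {e}") from None
    return out


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    rows = [
        {
            "protein_id": r.protein_id,
            "label": r.label,
            "function_codes": ";".join(sorted(r.function_codes)),
            "localization_code": r.localization_code or "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tm-weight table
# ---------------------------------------------------------------------------


def read_tm_table(path: str | Path, low_threshold: float | None = None) -> TmWeightTable:
    """Read a 400-row dipeptide/weight TSV.

    The low-weight cutoff comes from (in priority order) the
    ``low_threshold`` argument or a ``# low_threshold: <x>`` comment line
    in the file.  Duplicate or missing dipeptides raise.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    file_threshold = None
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#") and "low_threshold" in line:
            file_threshold = float(line.split(":", 1)[1])
    # keep_default_na: the dipeptide "NA" must stay a string
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, dtype={"dipeptide": str})
    if not {"dipeptide", "weight"} <= set(df.columns):
        raise InputError(f"{path}: need columns dipeptide, weight")
    dups = df["dipeptide"][df["dipeptide"].duplicated()].tolist()
    if dups:
        raise InputError(f"{path}: duplicate dipeptides {sorted(set(dups))[:5]}")
    thr = low_threshold if low_threshold is not None else file_threshold
    if thr is None:
        raise InputError(f"{path}: no low_threshold given (argument or '# low_threshold:' line)")
    return TmWeightTable(dict(zip(df["dipeptide"], df["weight"].astype(float))), float(thr))


def write_tm_table(table: TmWeightTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# low_threshold: {table.low_threshold}\n")
        fh.write("dipeptide\tweight\n")
        for d in DIPEPTIDES:
            fh.write(f"{d}\t{table.weight[d]:.6g}\n")


def load_default_tm_table() -> TmWeightTable:
    """Load the packaged default Tm-weight table.

    The packaged table is a *synthetic* stand-in with a realistic category
    split (25% negative, 25% low); the dipeptide Tm-weight literature values
    are not redistributable here.  Supply your own table via
    :func:`read_tm_table` for analyses of real proteomes.
    """
    from importlib.resources import files

    path = files("coldcomp").joinpath("data/tm_weights_synthetic.tsv")
    return read_tm_table(str(path))


# ---------------------------------------------------------------------------
# growth curves
# ---------------------------------------------------------------------------

_GROWTH_COLS = ["organism_id", "temperature", "replicate", "time_h", "od600"]


def read_growth_csv(path: str | Path) -> list[GrowthCurve]:
    """Read replicate growth curves from long-format CSV.

    Columns: organism_id, temperature, replicate, time_h, od600.  One
    :class:`GrowthCurve` per (organism, temperature, replicate), ordered
    deterministically.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _GROWTH_COLS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    curves = []
    for (org, temp, rep), g in df.groupby(
        ["organism_id", "temperature", "replicate"], sort=True
    ):
        g = g.sort_values("time_h")
        curves.append(
            GrowthCurve(
                str(org),
                float(temp),
                int(rep),
                tuple(g["time_h"].astype(float)),
                tuple(g["od600"].astype(float)),
            )
        )
    return curves


def write_growth_csv(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od):
            rows.append(
                {
                    "organism_id": c.organism_id,
                    "temperature": c.temperature,
                    "replicate": c.replicate,
                    "time_h": t,
                    "od600": od,
                }
            )
    pd.DataFrame(rows, columns=_GROWTH_COLS).to_csv(path, index=False)


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (.5 rounds up)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
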
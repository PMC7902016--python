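"""Per-protein amino-acid composition and the derived Vf/VMf/Tn/Tln statistics.

For each protein we compute the percentage of each of the 20 residues, the
percentage of residues in the very-flexible class (Vf) and in the
very-plus-moderately-flexible class (VMf), and the percentage of the
protein's ``length - 1`` overlapping ordered dipeptides whose Tm weight is
negative (Tn) or negative-or-low (Tln).  Percentages, not fractions, are the
working scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import (
    AA_ALPHABET,
    AA_INDEX,
    FlexibilityScheme,
    InputError,
    ProteinRecord,
    TmWeightTable,
)

# byte-value -> alphabet index lookup for fast sequence encoding
_ENCODE = np.full(128, -1, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _ENCODE[ord(_a)] = _i


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a validated sequence to int indices into the alphabet."""
    idx = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if idx.min(initial=0) < 0:
        raise InputError("sequence contains non-standard letters")
    return idx.astype(np.intp)


@dataclass(frozen=True)
class CompositionProfile:
    """Composition summary of one protein.

    ``tn_pct``/``tln_pct`` are ``None`` (flagged undefined) for length-1
    proteins, which have no dipeptides; such proteins keep their residue
    metrics but are excluded from dipeptide aggregates downstream.
    """

    protein_id: str
    organism_id: str
    length: int
    aa_pct: Mapping[str, float]
    vf_pct: float
    vmf_pct: float
    tn_pct: float | None
    tln_pct: float | None

    @property
    def dipeptides_defined(self) -> bool:
        return self.tn_pct is not None


def aa_percentages(protein: ProteinRecord) -> dict[str, float]:
    """Percentage of each of the 20 amino acids in the sequence (zeros included)."""
    idx = encode_sequence(protein.sequence)
    counts = np.bincount(idx, minlength=20)
    pct = counts * (100.0 / idx.size)
    return {a: float(pct[i]) for i, a in enumerate(AA_ALPHABET)}


def flexibility_pct(
    protein: ProteinRecord, scheme: FlexibilityScheme | None = None
) -> tuple[float, float]:
    """(vf_pct, vmf_pct): % residues in the very-flexible set, and in the
    union of very- and moderately-flexible sets."""
    scheme = scheme or FlexibilityScheme()
    idx = encode_sequence(protein.sequence)
    vf_mask = np.array([a in scheme.very_flexible for a in AA_ALPHABET])
    mf_mask = np.array([a in scheme.moderately_flexible for a in AA_ALPHABET])
    counts = np.bincount(idx, minlength=20)
    n = idx.size
    vf = float(counts[vf_mask].sum() * 100.0 / n)
    vmf = float(counts[vf_mask | mf_mask].sum() * 100.0 / n)
    return vf, vmf


def dipeptide_pct(
    protein: ProteinRecord, table: TmWeightTable
) -> tuple[float | None, float | None]:
    """(tn_pct, tln_pct) over the length-1 overlapping ordered dipeptides.

    Returns ``(None, None)`` for single-residue proteins (no dipeptides).
    """
    if len(protein) < 2:
        return None, None
    idx = encode_sequence(protein.sequence)
    cat = table.category_matrix()[idx[:-1], idx[1:]]
    n = cat.size
    n_neg = int((cat == 0).sum())
    n_low = int((cat == 1).sum())
    return 100.0 * n_neg / n, 100.0 * (n_neg + n_low) / n


def profile_protein(
    protein: ProteinRecord,
    scheme: FlexibilityScheme,
    table: TmWeightTable,
    *,
    _masks=None,
    _catmat=None,
) -> CompositionProfile:
    idx = encode_sequence(protein.sequence)
    n = idx.size
    counts = np.bincount(idx, minlength=20)
    pct = counts * (100.0 / n)
    if _masks is None:
        vf_mask = np.array([a in scheme.very_flexible for a in AA_ALPHABET])
        vmf_mask = vf_mask | np.array([a in scheme.moderately_flexible for a in AA_ALPHABET])
    else:
        vf_mask, vmf_mask = _masks
    vf = float(counts[vf_mask].sum() * 100.0 / n)
    vmf = float(counts[vmf_mask].sum() * 100.0 / n)
    if n < 2:
        tn = tln = None
    else:
        cat = (_catmat if _catmat is not None else table.category_matrix())[idx[:-1], idx[1:]]
        nd = cat.size
        n_neg = int((cat == 0).sum())
        n_low = int((cat == 1).sum())
        tn = 100.0 * n_neg / nd
        tln = 100.0 * (n_neg + n_low) / nd
    return CompositionProfile(
        protein.protein_id,
        protein.organism_id,
        n,
        {a: float(pct[i]) for i, a in enumerate(AA_ALPHABET)},
        vf,
        vmf,
        tn,
        tln,
    )


def profile_proteome(
    proteins: Sequence[ProteinRecord],
    scheme: FlexibilityScheme | None = None,
    table: TmWeightTable | None = None,
) -> list[CompositionProfile]:
    """Profile every protein; deterministic order by protein_id."""
    if not proteins:
        raise InputError("empty protein list")
    scheme = scheme or FlexibilityScheme()
    if table is None:
        from .io_model import load_default_tm_table

        table = load_default_tm_table()
    vf_mask = np.array([a in scheme.very_flexible for a in AA_ALPHABET])
    vmf_mask = vf_mask | np.array([a in scheme.moderately_flexible for a in AA_ALPHABET])
    catmat = table.category_matrix()
    out = [
        profile_protein(p, scheme, table, _masks=(vf_mask, vmf_mask), _catmat=catmat)
        for p in proteins
    ]
    out.sort(key=lambda pr: pr.protein_id)
    return out


def profiles_to_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Long-to-wide export: one row per protein, 20 aa columns + derived metrics."""
    rows = []
    for p in profiles:
        row = {"protein_id": p.protein_id, "organism_id": p.organism_id, "length": p.length}
        row.update({a: p.aa_pct[a] for a in AA_ALPHABET})
        row.update({"Vf": p.vf_pct, "VMf": p.vmf_pct, "Tn": p.tn_pct, "Tln": p.tln_pct})
        rows.append(row)
    return pd.DataFrame(rows)


def write_profiles_tsv(profiles: Iterable[CompositionProfile], path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.6g")
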
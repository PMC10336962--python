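"""Sequence descriptors for charge assignment and bias analysis.

Charges are assigned per residue at a given pH by Henderson–Hasselbalch
rounding against the Nozaki–Tanford intrinsic pKa table: a titratable
group receives the integer charge of its fully (de)protonated form when
the mean protonation-state charge at that pH rounds away from zero, and 0
otherwise.  This reproduces the fixed {−1, 0, +1} charge endpoint that a
short constant-pH titration run converges to for well-separated pKa
values, without any stochastic step.

Composition descriptors follow the CIDER conventions: FCR = f+ + f−,
NCPR = |f+ − f−| with the fractions computed over side chains only
(termini excluded), mean Kyte–Doolittle hydropathy, and proline fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml
from Bio import SeqIO

__all__ = [
    "STANDARD_RESIDUES",
    "ChargeAssignment",
    "SequenceDescriptors",
    "load_pka_table",
    "load_kd_scale",
    "residue_mean_charge",
    "assign_charges",
    "descriptors",
    "read_fasta",
]

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def _load_yaml(name: str):
    with resources.files("idpbench.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_pka_table(path: str | Path | None = None) -> dict:
    """Intrinsic pKa table: {'sidechains': {res: {pka, kind}}, 'termini': {...}}."""
    if path is None:
        return _load_yaml("pka_nozaki_tanford.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def load_kd_scale(path: str | Path | None = None) -> dict[str, float]:
    """Kyte–Doolittle hydropathy values per one-letter residue code."""
    if path is None:
        return _load_yaml("kyte_doolittle.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ChargeAssignment:
    """Integer bead charges for one chain plus summary counts."""

    per_bead_charge: tuple[int, ...]
    net_charge: int
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        assert self.net_charge == sum(self.per_bead_charge)


@dataclass(frozen=True)
class SequenceDescriptors:
    fcr: float
    ncpr: float
    kd_hydrophobicity: float
    proline_fraction: float
    disorder_score: float | None = None


def _mean_charge(pka: float, kind: str, pH: float) -> float:
    """Mean charge of a titratable group at ``pH`` (Henderson–Hasselbalch)."""
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (pH - pka))
    if kind == "acid":
        return -1.0 / (1.0 + 10.0 ** (pka - pH))
    raise ValueError(f"unknown group kind {kind!r}")


def residue_mean_charge(residue: str, pH: float, pka_table: dict | None = None) -> float:
    """Mean side-chain charge of one residue at ``pH``; 0 for non-titratable."""
    tbl = pka_table if pka_table is not None else load_pka_table()
    entry = tbl["sidechains"].get(residue)
    if entry is None:
        return 0.0
    return _mean_charge(entry["pka"], entry["kind"], pH)


def _rounded(q: float) -> int:
    """Round a mean charge away from zero to {−1, 0, +1}."""
    if q >= 0.5:
        return 1
    if q <= -0.5:
        return -1
    return 0


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    for i, aa in enumerate(sequence):
        if aa not in STANDARD_RESIDUES:
            raise ValueError(f"unknown residue {aa!r} at position {i + 1}")
    return sequence


def assign_charges(
    sequence: str,
    pH: float = 7.0,
    pka_table: dict | None = None,
    termini_mode: str = "merged",
) -> ChargeAssignment:
    """Integer bead charges for ``sequence`` at ``pH``.

    termini_mode
        ``"merged"``: the N-terminal (+) and C-terminal (−) charges are
        added onto the first and last residue beads; a resulting ±2 is
        clamped back to ±1 with a warning, so per-bead charges stay in
        {−1, 0, +1} at the cost of one unit of net charge.
        ``"extra_beads"``: the termini become two dedicated beads flanking
        the chain, preserving the exact net charge.
    """
    sequence = _check_sequence(sequence)
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH must be in [0, 14], got {pH}")
    if termini_mode not in ("merged", "extra_beads"):
        raise ValueError(f"termini_mode must be 'merged' or 'extra_beads', got {termini_mode!r}")
    tbl = pka_table if pka_table is not None else load_pka_table()
    for aa in set(sequence):
        # default table covers everything; a user table may not
        if aa in "DEHCYKR" and aa not in tbl["sidechains"]:
            raise ValueError(f"pKa table has no entry for titratable residue {aa!r}")

    charges = [_rounded(residue_mean_charge(aa, pH, tbl)) for aa in sequence]
    n_term = _rounded(_mean_charge(tbl["termini"]["N"]["pka"], tbl["termini"]["N"]["kind"], pH))
    c_term = _rounded(_mean_charge(tbl["termini"]["C"]["pka"], tbl["termini"]["C"]["kind"], pH))

    if termini_mode == "extra_beads":
        charges = [n_term] + charges + [c_term]
    else:
        for idx, dq in ((0, n_term), (-1, c_term)):
            merged = charges[idx] + dq
            if abs(merged) > 1:
                warnings.warn(
                    "terminal charge clamped to +/-1 on an already charged "
                    "terminal bead; one unit of net charge is lost in 'merged' "
                    "mode (use termini_mode='extra_beads' to preserve it)",
                    stacklevel=2,
                )
                merged = max(-1, min(1, merged))
            charges[idx] = merged

    return ChargeAssignment(
        per_bead_charge=tuple(charges),
        net_charge=sum(charges),
        n_positive=sum(1 for q in charges if q > 0),
        n_negative=sum(1 for q in charges if q < 0),
    )


def descriptors(
    sequence: str,
    pH: float = 7.0,
    pka_table: dict | None = None,
    kd_scale: dict[str, float] | None = None,
    disorder_score: float | None = None,
) -> SequenceDescriptors:
    """Composition descriptors of ``sequence`` (termini excluded from fractions)."""
    sequence = _check_sequence(sequence)
    tbl = pka_table if pka_table is not None else load_pka_table()
    kd = kd_scale if kd_scale is not None else load_kd_scale()
    n = len(sequence)
    charges = [_rounded(residue_mean_charge(aa, pH, tbl)) for aa in sequence]
    f_pos = sum(1 for q in charges if q > 0) / n
    f_neg = sum(1 for q in charges if q < 0) / n
    return SequenceDescriptors(
        fcr=f_pos + f_neg,
        ncpr=abs(f_pos - f_neg),
        kd_hydrophobicity=sum(kd[aa] for aa in sequence) / n,
        proline_fraction=sequence.count("P") / n,
        disorder_score=disorder_score,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (name, sequence) pairs from a FASTA file.

    Sequences are upper-cased with line wraps and whitespace removed.
    """
    records = [
        (rec.id, str(rec.seq).replace(" ", "").upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    for name, seq in records:
        if not seq:
            raise ValueError(f"{path}: record {name!r} has an empty sequence")
    return records
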
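"""Male karyotype records and the base-chromosome-number counting rule.

Complement notation follows spider cytogenetics convention: ``26a`` means a
diploid complement of 26 acrocentric (one-armed) autosomes, ``14m`` fourteen
metacentric (two-armed) autosomes; the male sex-chromosome system is written
element by element with morphology subscripts, e.g. ``XaXa0`` (two acrocentric
Xs, no Y — the ancestral salticid X1X2O system), ``XaXaYa`` (neo-Y via a
single X-autosome fusion), ``XaXaXaYm`` (XXXY via two fusions).  A trailing
``?`` marks an uncertain score; a bare ``?`` marks an unknown value.

The *base number* of a karyotype is its ancestral-equivalent diploid autosome
count: the observed autosomes, plus two per autosome pair inferred to be
bound into the sex-chromosome system (one pair for XXY, two for XXXY).  Each
X-autosome fusion consumes one autosome pair while creating one neo-Y-linked
element, so fusions leave the base number invariant; only genuine pair gains
and losses move it.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SexSystem",
    "KaryotypeRecord",
    "BaseNumber",
    "ComplementSummary",
    "KaryotypeError",
    "parse_complement",
    "parse_sex_notation",
    "parse_karyotype_table",
    "write_karyotype_table",
    "base_number",
    "y_state",
    "summarize_complements",
]


class KaryotypeError(ValueError):
    """Invalid complement notation or inconsistent record."""


class SexSystem(str, Enum):
    """Male sex-chromosome system, by element count (morphology aside)."""

    X0 = "X0"
    XX0 = "XX0"
    XXY = "XXY"
    XXXY = "XXXY"
    XXXY_OR_XYYY = "XXXY_OR_XYYY"

    @property
    def has_y(self) -> bool:
        return self in (SexSystem.XXY, SexSystem.XXXY, SexSystem.XXXY_OR_XYYY)

    @property
    def n_fused_pairs(self) -> int | None:
        """Autosome pairs inferred bound into the system (None if the
        counting rule does not cover the system)."""
        if self in (SexSystem.X0,):
            return None
        if self is SexSystem.XX0:
            return 0
        if self is SexSystem.XXY:
            return 1
        return 2  # XXXY, and XXXY-or-XYYY (either reading implies two fusions)


_COMPLEMENT_RE = re.compile(r"^(?:(\d+)([am]))+\??$")
_COMPLEMENT_PART = re.compile(r"(\d+)([am])")
_SEX_TOKEN = re.compile(r"([XY])([am]?)")


def parse_complement(text: str) -> tuple[int | None, int, int, bool]:
    """Parse an autosome complement string.

    Returns ``(diploid_total, n_acrocentric, n_metacentric, uncertain)``;
    a bare ``"?"`` yields ``(None, 0, 0, True)``.
    """
    text = text.strip()
    if text == "?":
        return None, 0, 0, True
    if not _COMPLEMENT_RE.match(text):
        raise KaryotypeError(f"unparseable complement string: {text!r}")
    uncertain = text.endswith("?")
    acro = meta = 0
    for count, morph in _COMPLEMENT_PART.findall(text):
        if morph == "a":
            acro += int(count)
        else:
            meta += int(count)
    return acro + meta, acro, meta, uncertain


def parse_sex_notation(text: str) -> tuple[SexSystem, tuple[str, ...], bool]:
    """Parse a sex-chromosome string such as ``XaXa0`` or ``XmXaYm``.

    Alternative readings separated by ``|`` (e.g. ``XaXaXaYm|XmYaYaYa``)
    collapse to :attr:`SexSystem.XXXY_OR_XYYY`.  Returns
    ``(system, per-element morphologies of the first reading, uncertain)``.
    """
    text = text.strip()
    uncertain = text.endswith("?")
    body = text.rstrip("?")
    readings = [r.strip() for r in body.split("|")]

    def one(reading: str) -> tuple[tuple[int, int], tuple[str, ...]]:
        stripped = reading.rstrip("0")
        tokens = _SEX_TOKEN.findall(stripped)
        if not tokens or "".join(c + m for c, m in tokens) != stripped:
            raise KaryotypeError(f"unparseable sex-chromosome string: {text!r}")
        n_x = sum(1 for c, _ in tokens if c == "X")
        n_y = sum(1 for c, _ in tokens if c == "Y")
        morphs = tuple(m or "a" for _, m in tokens)
        return (n_x, n_y), morphs

    counts = []
    morphs0: tuple[str, ...] = ()
    for i, reading in enumerate(readings):
        (n_x, n_y), morphs = one(reading)
        counts.append((n_x, n_y))
        if i == 0:
            morphs0 = morphs
    systems = []
    for n_x, n_y in counts:
        try:
            systems.append({
                (1, 0): SexSystem.X0,
                (2, 0): SexSystem.XX0,
                (2, 1): SexSystem.XXY,
                (3, 1): SexSystem.XXXY,
                (1, 3): SexSystem.XXXY_OR_XYYY,  # XYYY reading
            }[(n_x, n_y)])
        except KeyError:
            raise KaryotypeError(
                f"unrecognized sex-chromosome system ({n_x} X, {n_y} Y): {text!r}"
            ) from None
    if len(set(systems)) == 1:
        return systems[0], morphs0, uncertain
    if set(systems) <= {SexSystem.XXXY, SexSystem.XXXY_OR_XYYY}:
        return SexSystem.XXXY_OR_XYYY, morphs0, uncertain
    raise KaryotypeError(f"irreconcilable alternative readings: {text!r}")


@dataclass(frozen=True)
class KaryotypeRecord:
    """One species' male chromosome complement, with uncertainty flags."""

    species: str
    diploid_autosomes: int | None
    acrocentric_autosomes: int
    metacentric_autosomes: int
    sex_system: SexSystem
    sex_morphologies: tuple[str, ...] = ()
    y_present: bool = False
    autosomes_uncertain: bool = False
    sex_uncertain: bool = False
    n_specimens: int = 0
    n_full_nuclei: int = 0
    notes: str = ""

    def __post_init__(self):
        if self.diploid_autosomes is not None:
            if self.acrocentric_autosomes + self.metacentric_autosomes \
                    != self.diploid_autosomes:
                raise KaryotypeError(
                    f"{self.species}: morphology counts do not sum to "
                    f"{self.diploid_autosomes}")
            if self.diploid_autosomes % 2:
                raise KaryotypeError(
                    f"{self.species}: odd diploid autosome count "
                    f"{self.diploid_autosomes} (autosomes occur in pairs)")
        if self.y_present != self.sex_system.has_y:
            raise KaryotypeError(
                f"{self.species}: y_present={self.y_present} inconsistent "
                f"with sex system {self.sex_system.value}")
        if self.n_specimens < 0 or self.n_full_nuclei < 0:
            raise KaryotypeError(f"{self.species}: negative evidence counts")

    @property
    def n_autosome_bivalents(self) -> int | None:
        """Autosomal bivalents at meiosis I (half the diploid count)."""
        if self.diploid_autosomes is None:
            return None
        return self.diploid_autosomes // 2

    def complement_string(self) -> str:
        if self.diploid_autosomes is None:
            return "?"
        parts = ""
        if self.acrocentric_autosomes:
            parts += f"{self.acrocentric_autosomes}a"
        if self.metacentric_autosomes:
            parts += f"{self.metacentric_autosomes}m"
        if not parts:
            parts = "0a"
        return parts + ("?" if self.autosomes_uncertain else "")


@dataclass(frozen=True)
class BaseNumber:
    """Inferred ancestral-equivalent diploid autosome count."""

    value: int | None
    uncertain: bool = False


def base_number(record: KaryotypeRecord, mode: str = "default") -> BaseNumber:
    """Apply the counting rule: XX0 keeps the observed autosome count,
    XXY adds 2 (one pair bound), XXXY adds 4 (two pairs bound).

    An X0 system with metacentric autosomes (a completed Robertsonian
    fusion series) is outside the rule; by default it scores UNKNOWN.
    With ``mode="arm_equivalents"`` it scores the total autosome *arm*
    count instead, since Robertsonian fusions conserve arm number.
    """
    if mode not in ("default", "arm_equivalents"):
        raise ValueError(f"unknown mode: {mode!r}")
    uncertain = record.autosomes_uncertain or record.sex_uncertain
    if record.diploid_autosomes is None:
        return BaseNumber(None, True)
    fused = record.sex_system.n_fused_pairs
    if fused is None:
        if mode == "arm_equivalents":
            arms = record.acrocentric_autosomes + 2 * record.metacentric_autosomes
            return BaseNumber(arms, True)
        return BaseNumber(None, True)
    return BaseNumber(record.diploid_autosomes + 2 * fused, uncertain)


def y_state(record: KaryotypeRecord) -> int:
    """Binary neo-Y character: 1 iff a Y chromosome is present."""
    return int(record.y_present)


# -- table I/O -------------------------------------------------------------

_REQUIRED_COLUMNS = ("species", "autosomes", "sex_system", "y_present")


def parse_karyotype_table(source) -> list[KaryotypeRecord]:
    """Read a karyotype TSV (columns: species, autosomes, sex_system,
    y_present, exx, nuc, notes) into validated records.

    ``?``-suffixed cells set the matching uncertainty flag but keep the
    face value; a bare ``?`` in ``y_present`` defers to the sex notation
    and flags the sex score uncertain.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        df = pd.read_csv(source, sep="\t", dtype=str)
    else:
        df = pd.read_csv(io.StringIO(str(source)), sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise KaryotypeError(f"karyotype table lacks column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        if pd.isna(row["species"]):
            continue
        total, acro, meta, auto_unc = parse_complement(str(row["autosomes"]))
        system, morphs, sex_unc = parse_sex_notation(str(row["sex_system"]))
        y_cell = str(row["y_present"]).strip().lower()
        if y_cell in ("?", "nan", ""):
            y = system.has_y
            sex_unc = True
        elif y_cell in ("yes", "true", "1"):
            y = True
        elif y_cell in ("no", "false", "0"):
            y = False
        else:
            raise KaryotypeError(f"bad y_present value: {row['y_present']!r}")
        records.append(KaryotypeRecord(
            species=str(row["species"]).strip(),
            diploid_autosomes=total,
            acrocentric_autosomes=acro,
            metacentric_autosomes=meta,
            sex_system=system,
            sex_morphologies=morphs,
            y_present=y,
            autosomes_uncertain=auto_unc,
            sex_uncertain=sex_unc,
            n_specimens=_int_or_zero(row.get("exx")),
            n_full_nuclei=_int_or_zero(row.get("nuc")),
            notes="" if pd.isna(row.get("notes")) else str(row.get("notes")),
        ))
    return records


def _int_or_zero(value) -> int:
    if value is None or pd.isna(value):
        return 0
    return int(str(value).strip())


def _sex_string(record: KaryotypeRecord) -> str:
    if record.sex_system is SexSystem.XXXY_OR_XYYY:
        body = "XaXaXaYm|XmYaYaYa"
    else:
        n_x = record.sex_system.value.count("X")
        n_y = record.sex_system.value.count("Y")
        morphs = list(record.sex_morphologies) or ["a"] * (n_x + n_y)
        body = "".join(f"X{m}" for m in morphs[:n_x])
        body += "".join(f"Y{m}" for m in morphs[n_x:n_x + n_y])
        if n_y == 0:
            body += "0"
    return body + ("?" if record.sex_uncertain else "")


def write_karyotype_table(records: Sequence[KaryotypeRecord], path=None) -> str:
    """Serialize records back to the TSV layout of :func:`parse_karyotype_table`."""
    df = pd.DataFrame({
        "species": [r.species for r in records],
        "autosomes": [r.complement_string() for r in records],
        "sex_system": [_sex_string(r) for r in records],
        "y_present": ["yes" if r.y_present else "no" for r in records],
        "exx": [r.n_specimens for r in records],
        "nuc": [r.n_full_nuclei for r in records],
        "notes": [r.notes for r in records],
    })
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text)
    return text


# -- summaries -------------------------------------------------------------

@dataclass(frozen=True)
class ComplementSummary:
    """Face-value tallies over a set of karyotype records."""

    standard_species: tuple[str, ...]   # 26 all-acrocentric + XX0
    extra_pair_species: tuple[str, ...]  # 28 autosomes + XX0
    neo_y_species: tuple[str, ...]
    other_species: tuple[str, ...]
    total: int

    @property
    def n_standard(self) -> int:
        return len(self.standard_species)

    @property
    def n_extra_pair(self) -> int:
        return len(self.extra_pair_species)

    @property
    def n_neo_y(self) -> int:
        return len(self.neo_y_species)


def summarize_complements(records: Iterable[KaryotypeRecord]) -> ComplementSummary:
    """Tally the usual salticid complement (26 acrocentric autosomes + XX0),
    the 28-autosome XX0 variants, and the neo-Y species, at face value."""
    records = list(records)
    if not records:
        raise KaryotypeError("summarize_complements requires at least one record")
    standard, extra, neo_y, other = [], [], [], []
    for r in records:
        if r.y_present:
            neo_y.append(r.species)
        elif (r.sex_system is SexSystem.XX0 and r.diploid_autosomes == 26
              and r.metacentric_autosomes == 0):
            standard.append(r.species)
        elif r.sex_system is SexSystem.XX0 and r.diploid_autosomes == 28:
            extra.append(r.species)
        else:
            other.append(r.species)
    return ComplementSummary(
        tuple(standard), tuple(extra), tuple(neo_y), tuple(other), len(records))
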
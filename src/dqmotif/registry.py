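"""Allele registry: mature-chain amino-acid residues for DQA1/DQB1 alleles.

The HLA-DQ molecule is an alpha/beta heterodimer encoded by *DQA1* and *DQB1*.
Each allele's mature chain is stored as an ordered map from structural position
labels to single-letter amino acids.  Position labels follow the structural
numbering convention of the source data (the alpha chain carries an extra
N-terminal position "a1" ahead of the numeric positions 1..232; the beta chain
runs 1..237) and are treated as opaque strings: the registry never renumbers
sequences itself.

The shipped fixture covers the nine-residue motif panel
(alpha a1/44/157/196, beta 9/30/57/70/135) plus a handful of additional
polymorphic positions; full-length chains are supported but not required.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

ALPHA, BETA = "alpha", "beta"
_CHAIN_BOUNDS = {ALPHA: 232, BETA: 237}
_LOCUS_CHAIN = {"DQA1": ALPHA, "DQB1": BETA}


class RegistryError(ValueError):
    """Raised for malformed fixtures or invalid lookups."""


@dataclass(frozen=True)
class PositionLabel:
    """A structural position on one chain, e.g. ('alpha', '44') or ('beta', '57')."""

    chain: str
    label: str

    def __post_init__(self) -> None:
        if self.chain not in (ALPHA, BETA):
            raise RegistryError(f"unknown chain {self.chain!r}")
        if self.label == "a1":
            if self.chain != ALPHA:
                raise RegistryError("position 'a1' exists only on the alpha chain")
        else:
            try:
                n = int(self.label)
            except ValueError:
                raise RegistryError(f"position label {self.label!r} is not numeric") from None
            if not 1 <= n <= _CHAIN_BOUNDS[self.chain]:
                raise RegistryError(
                    f"position {self.label} outside {self.chain} chain bounds "
                    f"1..{_CHAIN_BOUNDS[self.chain]}"
                )

    def sort_key(self) -> tuple:
        # 'a1' precedes numeric positions on the alpha chain
        return (self.chain, 0 if self.label == "a1" else 1,
                0 if self.label == "a1" else int(self.label))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        prefix = "α" if self.chain == ALPHA else "β"
        return f"{prefix}{self.label}"


def normalize_allele(name: str) -> str:
    """Truncate an IMGT-style allele name to two-field resolution.

    'DQA1*05:01:01:02' -> 'DQA1*05:01'.  Two-field names pass through.
    """
    name = name.strip()
    if "*" not in name:
        raise RegistryError(f"malformed allele name {name!r}")
    locus, _, fields = name.partition("*")
    parts = fields.split(":")
    if len(parts) < 2:
        raise RegistryError(f"allele {name!r} below two-field resolution")
    return f"{locus}*{parts[0]}:{parts[1]}"


def allele_chain(name: str) -> str:
    locus = name.split("*", 1)[0]
    try:
        return _LOCUS_CHAIN[locus]
    except KeyError:
        raise RegistryError(f"locus {locus!r} is not DQA1/DQB1") from None


@dataclass
class AlleleSequence:
    """Residues of one allele's mature chain at the registered positions."""

    allele_name: str
    chain: str
    residues: dict[PositionLabel, str]

    def __post_init__(self) -> None:
        if allele_chain(self.allele_name) != self.chain:
            raise RegistryError(
                f"allele {self.allele_name} does not encode the {self.chain} chain"
            )
        for pos, aa in self.residues.items():
            if pos.chain != self.chain:
                raise RegistryError(f"position {pos} on wrong chain for {self.allele_name}")
            if aa not in AMINO_ACIDS:
                raise RegistryError(
                    f"{self.allele_name} position {pos}: {aa!r} is not a standard amino acid"
                )

    def positions(self) -> list[PositionLabel]:
        return sorted(self.residues, key=PositionLabel.sort_key)


def _default_alpha() -> list[PositionLabel]:
    return [PositionLabel(ALPHA, p) for p in ("a1", "44", "157", "196")]


def _default_beta() -> list[PositionLabel]:
    return [PositionLabel(BETA, p) for p in ("9", "30", "57", "70", "135")]


@dataclass
class ResiduePanel:
    """The ordered residue positions whose amino acids form a DQ motif.

    Defaults to the nine critical positions (four alpha, five beta); the panel
    is an input to this pipeline, selected upstream by hierarchically organized
    haplotype analysis.
    """

    alpha_positions: list[PositionLabel] = field(default_factory=_default_alpha)
    beta_positions: list[PositionLabel] = field(default_factory=_default_beta)

    def __post_init__(self) -> None:
        if not self.alpha_positions or not self.beta_positions:
            raise RegistryError("residue panel must name positions on both chains")
        allpos = self.alpha_positions + self.beta_positions
        if len(set(allpos)) != len(allpos):
            raise RegistryError("duplicate positions in residue panel")

    @property
    def positions(self) -> list[PositionLabel]:
        return list(self.alpha_positions) + list(self.beta_positions)

    def __len__(self) -> int:
        return len(self.alpha_positions) + len(self.beta_positions)


class AlleleRegistry:
    """Collection of AlleleSequence objects keyed by two-field allele name."""

    def __init__(self, alleles: list[AlleleSequence]):
        self._alleles: dict[str, AlleleSequence] = {}
        for a in alleles:
            key = normalize_allele(a.allele_name)
            if key in self._alleles and key == a.allele_name:
                raise RegistryError(f"duplicate allele {key}")
            self._alleles.setdefault(a.allele_name, a)
            self._alleles.setdefault(key, a)
        if not self._alleles:
            raise RegistryError("no alleles")

    def get(self, name: str) -> AlleleSequence:
        if name in self._alleles:
            return self._alleles[name]
        key = normalize_allele(name)
        if key in self._alleles:
            return self._alleles[key]
        raise RegistryError(f"allele {name} not in registry")

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except RegistryError:
            return False

    def allele_names(self) -> list[str]:
        # unique underlying sequences, by their declared names
        seen, out = set(), []
        for a in self._alleles.values():
            if id(a) not in seen:
                seen.add(id(a))
                out.append(a.allele_name)
        return sorted(out)

    def validate_panel(self, panel: ResiduePanel) -> None:
        for name in self.allele_names():
            a = self.get(name)
            want = panel.alpha_positions if a.chain == ALPHA else panel.beta_positions
            missing = [p for p in want if p not in a.residues]
            if missing:
                raise RegistryError(
                    f"allele {name} missing motif position(s) "
                    + ", ".join(str(p) for p in missing)
                )


def residue_at(allele: AlleleSequence, pos: PositionLabel) -> str:
    """Pure lookup of the amino acid at one structural position."""
    if pos.chain != allele.chain:
        raise RegistryError(
            f"position {pos} is on the {pos.chain} chain but {allele.allele_name} "
            f"encodes the {allele.chain} chain"
        )
    try:
        return allele.residues[pos]
    except KeyError:
        raise RegistryError(f"position {pos} not registered for {allele.allele_name}") from None


def load_registry(path, panel: ResiduePanel | None = None) -> AlleleRegistry:
    """Read an allele-residue TSV into a registry.

    Format: one row per allele; columns ``allele``, ``chain``, then one column
    per position label.  A position column applies to a row when its cell is
    non-empty.  Lines starting with '#' are comments.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise RegistryError(f"cannot parse registry file {path}: {exc}") from exc
    if df.empty:
        raise RegistryError("no alleles")
    for col in ("allele", "chain"):
        if col not in df.columns:
            raise RegistryError(f"registry file missing required column {col!r}")
    pos_cols = [c for c in df.columns if c not in ("allele", "chain")]

    alleles: list[AlleleSequence] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        line = i + 2  # header line is 1
        name, chain = str(row["allele"]).strip(), str(row["chain"]).strip()
        if chain not in (ALPHA, BETA):
            raise RegistryError(f"line {line}: unknown chain {chain!r}")
        if name in seen:
            raise RegistryError(f"line {line}: duplicate allele {name}")
        seen.add(name)
        residues: dict[PositionLabel, str] = {}
        for c in pos_cols:
            cell = row[c]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                pos = PositionLabel(chain, c)
            except RegistryError:
                continue  # column belongs to the other chain's label space
            residues[pos] = str(cell).strip()
        if not residues:
            raise RegistryError(f"line {line}: no residues for allele {name}")
        try:
            alleles.append(AlleleSequence(name, chain, residues))
        except RegistryError as exc:
            raise RegistryError(f"line {line}: {exc}") from exc

    reg = AlleleRegistry(alleles)
    if panel is not None:
        reg.validate_panel(panel)
    return reg


def load_default_registry(panel: ResiduePanel | None = None) -> AlleleRegistry:
    """Load the packaged DQ allele fixture."""
    ref = importlib.resources.files("dqmotif.data") / "dq_registry.tsv"
    with importlib.resources.as_file(ref) as path:
        return load_registry(path, panel=panel or ResiduePanel())


def polymorphic_positions(registry: AlleleRegistry, haplotypes) -> list[PositionLabel]:
    """Positions with >= 2 distinct amino acids across the given DQ haplotypes.

    ``haplotypes`` is an iterable of (dqa1, dqb1) allele-name pairs.  Both
    chains are scanned; the result is sorted by chain then position.
    """
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise RegistryError("haplotype set is empty")
    columns: dict[PositionLabel, set[str]] = {}
    for dqa1, dqb1 in haplotypes:
        for allele in (registry.get(dqa1), registry.get(dqb1)):
            for pos, aa in allele.residues.items():
                columns.setdefault(pos, set()).add(aa)
    poly = [pos for pos, aas in columns.items() if len(aas) >= 2]
    return sorted(poly, key=PositionLabel.sort_key)
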
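"""MDL V2000 molfile, SD file, RXN and RD file reading and writing.

The V2000 connection table is parsed by fixed columns with a whitespace
fallback for slightly off-format files.  Charges are taken from the
atom-block charge code unless any ``M  CHG`` property line is present, in
which case the property block supersedes every atom-block charge (and
likewise ``M  RAD`` for radicals), as the format specifies.

A "tweaked" dialect is supported for persisting aromaticity perception
inside spec-unused columns: the atom-block ``rrr`` not-used field (columns
55-57) carries a per-atom aromatic flag, the bond-block ``xxx`` not-used
field (columns 13-15) a per-bond flag, and the header program line carries
the signature token ``CMTWEAK``.  Conforming readers ignore all three, so a
tweaked file parses as the plain structure everywhere else.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, TextIO

TWEAK_SIGNATURE = "CMTWEAK"

#: atom-block charge codes of the V2000 spec (0 = none, 4 = doublet radical)
_CHARGE_CODE_TO_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}
_CHARGE_TO_CHARGE_CODE = {v: k for k, v in _CHARGE_CODE_TO_CHARGE.items()}


class Radical(enum.IntEnum):
    NONE = 0
    SINGLET = 1
    DOUBLET = 2
    TRIPLET = 3


class BondOrder(enum.IntEnum):
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC_INPUT = 4


class BondStereo(enum.IntEnum):
    NONE = 0
    UP = 1
    EITHER = 4
    DOWN = 6


class MolfileError(ValueError):
    """Malformed connection table; carries the offending 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass
class RawAtom:
    element: str
    charge: int = 0
    isotope_delta: int = 0
    radical: Radical = Radical.NONE
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    atom_map: int = 0
    aromatic_flag: bool = False  # populated only from tweaked files


@dataclass
class RawBond:
    a1: int  # 1-based
    a2: int
    order: BondOrder = BondOrder.SINGLE
    stereo: BondStereo = BondStereo.NONE
    aromatic_flag: bool = False


@dataclass
class MolfileDocument:
    title: str = ""
    program: str = ""
    comment: str = ""
    atoms: list[RawAtom] = field(default_factory=list)
    bonds: list[RawBond] = field(default_factory=list)
    tweak_flag: bool = False

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def is_3d(self) -> bool:
        return any(abs(a.z) > 1e-9 for a in self.atoms)


@dataclass
class ReactionDocument:
    reactants: list[MolfileDocument] = field(default_factory=list)
    products: list[MolfileDocument] = field(default_factory=list)

    @property
    def atom_maps(self) -> list[tuple[str, int, int, int]]:
        """(side, molecule index, atom index, map class) for mapped atoms."""
        out = []
        for side, mols in (("reactant", self.reactants), ("product", self.products)):
            for mi, mol in enumerate(mols):
                for ai, atom in enumerate(mol.atoms):
                    if atom.atom_map:
                        out.append((side, mi, ai, atom.atom_map))
        return out


def _int_field(line: str, start: int, end: int, lineno: int, default: int | None = None) -> int:
    text = line[start:end].strip()
    if not text:
        if default is None:
            raise MolfileError(f"missing integer in columns {start + 1}-{end}", lineno)
        return default
    try:
        return int(text)
    except ValueError:
        raise MolfileError(f"bad integer {text!r} in columns {start + 1}-{end}", lineno) from None


def _float_field(line: str, start: int, end: int, lineno: int) -> float:
    text = line[start:end].strip()
    if not text:
        return 0.0
    try:
        return float(text)
    except ValueError:
        raise MolfileError(f"bad coordinate {text!r}", lineno) from None


def parse_molfile(text: str, _line_offset: int = 0) -> MolfileDocument:
    """Parse a V2000 connection table.

    Raises :class:`MolfileError` (with a line number) on malformed counts
    lines, truncated blocks or V3000 input.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise MolfileError("molfile shorter than header + counts line", _line_offset + len(lines))
    doc = MolfileDocument(
        title=lines[0].rstrip(),
        program=lines[1].rstrip(),
        comment=lines[2].rstrip(),
    )
    counts = lines[3]
    if "V3000" in counts:
        raise MolfileError("V3000 connection tables are not supported", _line_offset + 4)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except ValueError:
        raise MolfileError(f"malformed counts line {counts!r}", _line_offset + 4) from None
    doc.tweak_flag = TWEAK_SIGNATURE in doc.program

    if len(lines) < 4 + n_atoms + n_bonds:
        raise MolfileError(
            f"truncated: counts line promises {n_atoms} atoms / {n_bonds} bonds",
            _line_offset + len(lines),
        )

    for i in range(n_atoms):
        lineno = _line_offset + 5 + i
        line = lines[4 + i]
        if len(line) < 34 and len(line.split()) >= 4:
            # whitespace fallback for non-column-aligned writers
            parts = line.split()
            atom = RawAtom(element=parts[3],
                           x=float(parts[0]), y=float(parts[1]), z=float(parts[2]))
        else:
            symbol = line[31:34].strip()
            if not symbol:
                raise MolfileError("empty atom symbol", lineno)
            atom = RawAtom(
                element=symbol,
                x=_float_field(line, 0, 10, lineno),
                y=_float_field(line, 10, 20, lineno),
                z=_float_field(line, 20, 30, lineno),
                isotope_delta=_int_field(line, 34, 36, lineno, 0),
                charge=_CHARGE_CODE_TO_CHARGE.get(_int_field(line, 36, 39, lineno, 0), 0),
            )
            if _int_field(line, 36, 39, lineno, 0) == 4:
                atom.radical = Radical.DOUBLET
            if doc.tweak_flag and _int_field(line, 54, 57, lineno, 0) == 1:
                atom.aromatic_flag = True
            atom.atom_map = _int_field(line, 60, 63, lineno, 0)
        doc.atoms.append(atom)

    for i in range(n_bonds):
        lineno = _line_offset + 5 + n_atoms + i
        line = lines[4 + n_atoms + i]
        a1 = _int_field(line, 0, 3, lineno)
        a2 = _int_field(line, 3, 6, lineno)
        order_code = _int_field(line, 6, 9, lineno, 1)
        if a1 == a2 or not (1 <= a1 <= n_atoms) or not (1 <= a2 <= n_atoms):
            raise MolfileError(f"bond endpoints {a1}-{a2} out of range", lineno)
        try:
            order = BondOrder(order_code)
        except ValueError:
            raise MolfileError(f"unsupported bond type {order_code}", lineno) from None
        stereo_code = _int_field(line, 9, 12, lineno, 0)
        stereo = BondStereo(stereo_code) if stereo_code in (0, 1, 4, 6) else BondStereo.NONE
        bond = RawBond(a1=a1, a2=a2, order=order, stereo=stereo)
        if doc.tweak_flag and _int_field(line, 12, 15, lineno, 0) == 1:
            bond.aromatic_flag = True
        doc.bonds.append(bond)

    # properties block: M CHG / M ISO / M RAD supersede atom-block columns
    saw_chg_or_rad = False
    for j in range(4 + n_atoms + n_bonds, len(lines)):
        line = lines[j]
        if line.startswith("M  END"):
            break
        if line.startswith(("M  CHG", "M  RAD")):
            if not saw_chg_or_rad:
                for atom in doc.atoms:
                    atom.charge = 0
                    atom.radical = Radical.NONE
                saw_chg_or_rad = True
            _apply_property(doc, line, _line_offset + j + 1)
        elif line.startswith("M  ISO"):
            _apply_property(doc, line, _line_offset + j + 1)
    return doc


def _apply_property(doc: MolfileDocument, line: str, lineno: int) -> None:
    kind = line[3:6]
    try:
        n = int(line[6:9])
        for k in range(n):
            aidx = int(line[9 + 8 * k: 13 + 8 * k])
            value = int(line[13 + 8 * k: 17 + 8 * k])
            atom = doc.atoms[aidx - 1]
            if kind == "CHG":
                atom.charge = value
            elif kind == "ISO":
                atom.isotope_delta = value
            elif kind == "RAD":
                atom.radical = Radical(value)
    except (ValueError, IndexError):
        raise MolfileError(f"malformed property line {line!r}", lineno) from None


def write_molfile(mol, tweaked: bool = False, title: str = "") -> str:
    """Render a document or perceived molecule as a V2000 molfile string.

    ``tweaked=True`` additionally stores the aromaticity flags (the input
    must then expose per-atom/per-bond ``aromatic`` attributes, i.e. come
    from perception or from a tweaked parse).  Molecules beyond the V2000
    capacity of 999 atoms or bonds are rejected.
    """
    atoms = mol.atoms
    bonds = mol.bonds
    # perceived molecules index bonds from 0, documents from 1
    offset = 1 if getattr(mol, "perceived", None) is not None else 0
    if len(atoms) > 999 or len(bonds) > 999:
        raise MolfileError("V2000 capacity exceeded (>999 atoms or bonds)")
    program = f"  {TWEAK_SIGNATURE}" if tweaked else "  molpat"
    out = [title or getattr(mol, "title", ""), program, getattr(mol, "comment", "")]
    out.append(f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000")

    charged = []
    isotopic = []
    radicals = []
    for i, atom in enumerate(atoms):
        aromatic = bool(getattr(atom, "aromatic", False) or getattr(atom, "aromatic_flag", False))
        rrr = 1 if (tweaked and aromatic) else 0  # "not used" column carries the flag
        out.append(
            f"{atom.x:10.4f}{atom.y:10.4f}{atom.z:10.4f} {atom.element:<3s}"
            f"{0:2d}{0:3d}{0:3d}{0:3d}{0:3d}{0:3d}{0:3d}{rrr:3d}{0:3d}"
            f"{atom.atom_map:3d}{0:3d}{0:3d}"
        )
        if atom.charge:
            charged.append((i + 1, atom.charge))
        if atom.isotope_delta:
            isotopic.append((i + 1, atom.isotope_delta))
        if atom.radical != Radical.NONE:
            radicals.append((i + 1, int(atom.radical)))

    for bond in bonds:
        aromatic = bool(getattr(bond, "aromatic", False) or getattr(bond, "aromatic_flag", False))
        xxx = 1 if (tweaked and aromatic) else 0
        order = getattr(bond, "order", BondOrder.SINGLE)
        out.append(f"{bond.a1 + offset:3d}{bond.a2 + offset:3d}{int(order):3d}"
                   f"{int(bond.stereo):3d}{xxx:3d}{0:3d}{0:3d}")

    for tag, entries in (("CHG", charged), ("ISO", isotopic), ("RAD", radicals)):
        for start in range(0, len(entries), 8):
            chunk = entries[start:start + 8]
            out.append(f"M  {tag}{len(chunk):3d}" + "".join(f"{a:4d}{v:4d}" for a, v in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n"


class SDFileError(ValueError):
    """Bad SD record; carries the 1-based record ordinal."""

    def __init__(self, message: str, record: int):
        self.record = record
        super().__init__(f"record {record}: {message}")


def iter_sdfile(stream: TextIO | str, tolerant: bool = False,
                ) -> Iterator[tuple[MolfileDocument, dict[str, str]]]:
    """Lazily yield ``(document, data fields)`` pairs from an SD file.

    Records are delimited by ``$$$$``.  By default a malformed record
    aborts iteration with :class:`SDFileError`; with ``tolerant=True`` it
    is skipped and iteration continues (batch-import behaviour).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    ordinal = 0
    record_lines: list[str] = []
    saw_any = False
    for raw in stream:
        line = raw.rstrip("\n")
        if line.strip() == "$$$$":
            ordinal += 1
            saw_any = True
            try:
                yield _parse_sd_record(record_lines, ordinal)
            except (MolfileError, SDFileError) as exc:
                if not tolerant:
                    if isinstance(exc, SDFileError):
                        raise
                    raise SDFileError(str(exc), ordinal) from exc
            record_lines = []
        else:
            record_lines.append(line)
    if any(l.strip() for l in record_lines):
        ordinal += 1
        if saw_any or any(l.strip() for l in record_lines):
            # final record lacking the $$$$ terminator
            err = SDFileError("missing $$$$ terminator", ordinal)
            if record_lines and any("M  END" in l for l in record_lines):
                # structurally complete record, only the delimiter is absent
                if tolerant:
                    try:
                        yield _parse_sd_record(record_lines, ordinal)
                        return
                    except (MolfileError, SDFileError):
                        return
            if not tolerant:
                raise err


def _parse_sd_record(lines: list[str], ordinal: int) -> tuple[MolfileDocument, dict[str, str]]:
    try:
        end = next(i for i, l in enumerate(lines) if l.startswith("M  END"))
    except StopIteration:
        raise SDFileError("no 'M  END' in record", ordinal) from None
    doc = parse_molfile("\n".join(lines[: end + 1]))
    fields: dict[str, str] = {}
    name = None
    buf: list[str] = []
    for line in lines[end + 1:]:
        if line.startswith(">"):
            if name is not None:
                fields[name] = "\n".join(buf).strip()
            lt, gt = line.find("<"), line.rfind(">")
            name = line[lt + 1: gt] if 0 <= lt < gt else line[1:].strip()
            buf = []
        elif name is not None:
            if line.strip() == "":
                fields[name] = "\n".join(buf).strip()
                name = None
                buf = []
            else:
                buf.append(line)
    if name is not None:
        fields[name] = "\n".join(buf).strip()
    return doc, fields


def write_sdfile(records: Iterable[tuple[object, dict[str, str]]], tweaked: bool = False) -> str:
    chunks = []
    for mol, fields in records:
        text = write_molfile(mol, tweaked=tweaked)
        for key, value in fields.items():
            text += f">  <{key}>\n{value}\n\n"
        chunks.append(text + "$$$$\n")
    return "".join(chunks)


def parse_rxnfile(text: str) -> ReactionDocument:
    """Parse an MDL RXN file into reactant and product documents."""
    lines = text.splitlines()
    if not lines or not lines[0].startswith("$RXN"):
        raise MolfileError("missing $RXN header", 1)
    if len(lines) < 5:
        raise MolfileError("truncated RXN header", len(lines))
    counts = lines[4]
    try:
        n_react = int(counts[0:3])
        n_prod = int(counts[3:6])
    except ValueError:
        raise MolfileError(f"malformed RXN counts line {counts!r}", 5) from None

    mol_starts = [i for i, l in enumerate(lines) if l.startswith("$MOL")]
    if len(mol_starts) != n_react + n_prod:
        raise MolfileError(
            f"RXN counts promise {n_react}+{n_prod} molecules, found {len(mol_starts)}", 5)
    mol_starts.append(len(lines))
    docs = []
    for k in range(n_react + n_prod):
        begin, end = mol_starts[k] + 1, mol_starts[k + 1]
        docs.append(parse_molfile("\n".join(lines[begin:end]), _line_offset=begin))
    rxn = ReactionDocument(reactants=docs[:n_react], products=docs[n_react:])
    _validate_maps(rxn)
    return rxn


def _validate_maps(rxn: ReactionDocument) -> None:
    r_classes = {a.atom_map for m in rxn.reactants for a in m.atoms if a.atom_map}
    p_classes = {a.atom_map for m in rxn.products for a in m.atoms if a.atom_map}
    lonely = r_classes ^ p_classes
    if lonely:
        raise MolfileError(f"atom map classes {sorted(lonely)} appear on one side only")


def write_rxnfile(rxn: ReactionDocument, name: str = "") -> str:
    out = [f"$RXN", name, "  molpat", "", f"{len(rxn.reactants):3d}{len(rxn.products):3d}"]
    for doc in list(rxn.reactants) + list(rxn.products):
        out.append("$MOL")
        out.append(write_molfile(doc).rstrip("\n"))
    return "\n".join(out) + "\n"


def iter_rdfile(stream: TextIO | str) -> Iterator[tuple[ReactionDocument | MolfileDocument, dict[str, str]]]:
    """Yield embedded RXN/MOL records plus ``$DTYPE/$DATUM`` data fields."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [l.rstrip("\n") for l in stream]
    i = 0
    current: list[str] | None = None
    kind = None
    fields: dict[str, str] = {}
    pending_dtype = None

    def flush():
        nonlocal current, kind, fields
        if current is not None:
            text = "\n".join(current)
            record = parse_rxnfile(text) if kind == "rxn" else parse_molfile(text)
            yield_value = (record, fields)
            current, kind, fields = None, None, {}
            return yield_value
        return None

    while i < len(lines):
        line = lines[i]
        if line.startswith("$RXN"):
            done = flush()
            if done:
                yield done
            current, kind = [line], "rxn"
        elif line.startswith("$MFMT"):
            done = flush()
            if done:
                yield done
            current, kind = [], "mol"
        elif line.startswith("$RFMT"):
            done = flush()
            if done:
                yield done
        elif line.startswith("$DTYPE"):
            pending_dtype = line[6:].strip()
        elif line.startswith("$DATUM"):
            if pending_dtype:
                fields[pending_dtype] = line[6:].strip()
                pending_dtype = None
        elif line.startswith("$RDFILE") or line.startswith("$DATM"):
            pass
        elif current is not None:
            current.append(line)
        i += 1
    done = flush()
    if done:
        yield done
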
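"""In-silico SRM assay design.

Tryptic digestion (Keil rule: cleave C-terminal to K/R unless followed by
P), monoisotopic peptide and fragment masses with fixed carbamidomethyl-C
and variable phospho-S/T/Y modifications, precursor m/z at charge 2 and
y-ion m/z at charges 1-2, and transition-list construction driven by a
spectral-library intensity table.

Masses are monoisotopic throughout.  Charging uses the proton mass (mass
of hydrogen minus the electron), so m/z = (M + z*m_p)/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from . import io as qio

#: Monoisotopic residue (amino-acid minus water) masses in Da.
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

WATER_MASS = 18.0105646863
PROTON_MASS = 1.00727646688
CARBAMIDOMETHYL_MASS = 57.021464
PHOSPHO_MASS = 79.966331


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty peptide/protein sequence")
    bad = set(sequence) - set(MONOISOTOPIC_RESIDUE_MASSES)
    if bad:
        raise ValueError(f"non-standard residue letters {sorted(bad)} in {sequence!r}")


@dataclass(frozen=True)
class Peptide:
    """A (possibly modified) peptide.

    ``carbamidomethyl`` applies the fixed +57.021464 Da alkylation shift to
    every cysteine (the global-run static modification).  ``var_mods`` is a
    tuple of (1-based position, mass shift) pairs; phospho entries
    (+79.966331 Da) are only permitted on S/T/Y residues.
    """

    sequence: str
    carbamidomethyl: bool = True
    var_mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        for pos, shift in self.var_mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside peptide of length "
                    f"{len(self.sequence)}"
                )
            if shift == PHOSPHO_MASS and self.sequence[pos - 1] not in "STY":
                raise ValueError(
                    f"phospho at position {pos} requires S/T/Y, found "
                    f"{self.sequence[pos - 1]!r}"
                )

    def modified_sequence(self) -> str:
        """Bracket notation, e.g. ``IGNC[+57.0215]PFSQR``."""
        shifts = {pos: 0.0 for pos in range(1, len(self.sequence) + 1)}
        if self.carbamidomethyl:
            for i, aa in enumerate(self.sequence, start=1):
                if aa == "C":
                    shifts[i] += CARBAMIDOMETHYL_MASS
        for pos, shift in self.var_mods:
            shifts[pos] += shift
        out = []
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if shifts[i]:
                out.append(f"[+{shifts[i]:.4f}]")
        return "".join(out)


def as_peptide(peptide: "Peptide | str") -> Peptide:
    return peptide if isinstance(peptide, Peptide) else Peptide(peptide)


# ---------------------------------------------------------------------------
# Digestion
# ---------------------------------------------------------------------------

def digest_trypsin(
    sequence: str,
    missed_cleavages: int = 0,
    proline_rule: bool = True,
) -> list[str]:
    """Tryptic peptides of ``sequence``.

    Cleaves C-terminal to K or R; with ``proline_rule`` (Keil) cleavage is
    suppressed when the next residue is proline.  With m missed cleavages
    every concatenation of up to m+1 adjacent fragments is also emitted.
    Order: all 0-miss fragments by position, then 1-miss concatenations by
    position, and so on.
    """
    _check_sequence(sequence)
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    cuts = [
        i + 1
        for i, aa in enumerate(sequence[:-1])
        if aa in "KR" and not (proline_rule and sequence[i + 1] == "P")
    ]
    bounds = [0, *cuts, len(sequence)]
    fragments = [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    peptides: list[str] = []
    for span in range(1, missed_cleavages + 2):
        for start in range(len(fragments) - span + 1):
            peptides.append("".join(fragments[start : start + span]))
    return peptides


# ---------------------------------------------------------------------------
# Masses and m/z
# ---------------------------------------------------------------------------

def monoisotopic_mass(peptide: "Peptide | str") -> float:
    """Neutral monoisotopic mass: residues + water + modification shifts."""
    p = as_peptide(peptide)
    mass = WATER_MASS + sum(MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in p.sequence)
    if p.carbamidomethyl:
        mass += CARBAMIDOMETHYL_MASS * p.sequence.count("C")
    mass += sum(shift for _, shift in p.var_mods)
    return mass


def precursor_mz(mass: float, charge: int = 2) -> float:
    """(M + z*proton)/z for a neutral mass M."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (mass + charge * PROTON_MASS) / charge


def _y_fragment_mass(p: Peptide, n: int) -> float:
    """Neutral mass of the C-terminal n residues plus water (the y fragment);
    internal helper that also accepts n == len (the full-length peptide)."""
    length = len(p.sequence)
    if not 1 <= n <= length:
        raise ValueError(f"y-ion length {n} outside 1..{length}")
    start = length - n  # 0-based index of first residue in the fragment
    seg = p.sequence[start:]
    mass = WATER_MASS + sum(MONOISOTOPIC_RESIDUE_MASSES[aa] for aa in seg)
    if p.carbamidomethyl:
        mass += CARBAMIDOMETHYL_MASS * seg.count("C")
    mass += sum(shift for pos, shift in p.var_mods if pos > start)
    return mass


def y_ion_mz(peptide: "Peptide | str", n: int, charge: int = 1) -> float:
    """m/z of the y_n fragment ion at the given charge (1 or 2 in this assay).

    n must be strictly less than the peptide length: the full-length "y"
    equals the precursor and is excluded from fragment lists.
    """
    p = as_peptide(peptide)
    if n >= len(p.sequence):
        raise ValueError(
            f"y-ion length {n} must be < peptide length {len(p.sequence)} "
            "(the full-length y ion is the precursor)"
        )
    return precursor_mz(_y_fragment_mass(p, n), charge)


def apply_phospho(peptide: "Peptide | str", site: tuple[str, int]) -> Peptide:
    """Add one phospho (+79.966331 Da) at ``site`` = (residue, 1-based position).

    The declared residue must match the sequence and be S, T or Y.
    """
    p = as_peptide(peptide)
    res, pos = site
    if not 1 <= pos <= len(p.sequence):
        raise ValueError(f"phosphosite position {pos} outside peptide")
    actual = p.sequence[pos - 1]
    if actual != res:
        raise ValueError(
            f"phosphosite at position {pos}: declared {res!r} but sequence has "
            f"{actual!r}"
        )
    if res not in "STY":
        raise ValueError(f"phosphosite at position {pos}: residue {res!r} not S/T/Y")
    return replace(p, var_mods=p.var_mods + ((pos, PHOSPHO_MASS),))


# ---------------------------------------------------------------------------
# Transition list construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionRow:
    """One SRM transition: a precursor (charge 2 by default) paired with a
    y-ion fragment at charge 1 or 2 and its spectral-library intensity."""

    protein: str
    peptide: str
    modified_sequence: str
    precursor_mz: float
    precursor_z: int
    fragment: str
    fragment_z: int
    fragment_mz: float
    library_intensity: float


def build_transition_list(
    fasta_records: list[tuple[str, str]],
    target_peptides: list[str],
    library: qio.LibraryType,
    top_n: int = 3,
    precursor_charge: int = 2,
    fragment_charges: tuple[int, ...] = (1, 2),
    min_y: int = 2,
) -> list[TransitionRow]:
    """Design transitions for each target peptide.

    Each peptide must be a proteotypic tryptic product of exactly one
    protein in ``fasta_records`` (0 missed cleavages).  Candidate fragments
    are y_n for n = min_y .. length-1 at every charge in
    ``fragment_charges``; the ``top_n`` by library intensity are kept (ties
    broken by larger n, then lower charge).  Rows are sorted by protein,
    peptide, then descending intensity.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    digests = {pid: set(digest_trypsin(seq)) for pid, seq in fasta_records}
    rows: list[TransitionRow] = []
    for pep_seq in target_peptides:
        hosts = [pid for pid, digest in digests.items() if pep_seq in digest]
        if not hosts:
            raise ValueError(
                f"peptide {pep_seq!r} is not a tryptic product of any supplied protein"
            )
        if len(hosts) > 1:
            raise ValueError(
                f"peptide {pep_seq!r} is not proteotypic: found in {sorted(hosts)}"
            )
        lib = library.get(pep_seq)
        if not lib:
            raise ValueError(f"spectral library has no fragments for peptide {pep_seq!r}")
        peptide = Peptide(pep_seq)
        pmz = precursor_mz(monoisotopic_mass(peptide), precursor_charge)
        candidates = []
        for n in range(min_y, len(pep_seq)):
            for z in fragment_charges:
                intensity = lib.get((f"y{n}", z), 0.0)
                candidates.append((intensity, n, z))
        # top_n by intensity; ties prefer longer fragments, then lower charge
        candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
        for intensity, n, z in candidates[:top_n]:
            rows.append(
                TransitionRow(
                    protein=hosts[0],
                    peptide=pep_seq,
                    modified_sequence=peptide.modified_sequence(),
                    precursor_mz=pmz,
                    precursor_z=precursor_charge,
                    fragment=f"y{n}",
                    fragment_z=z,
                    fragment_mz=y_ion_mz(peptide, n, z),
                    library_intensity=intensity,
                )
            )
    rows.sort(
        key=lambda r: (
            r.protein,
            r.peptide,
            -r.library_intensity,
            -int(r.fragment[1:]),
            r.fragment_z,
        )
    )
    return rows
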
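"""Parsing, validation and tokenization of modified phosphopeptides.

A peptide is written in a *compact* dialect in which the leading symbol
carries the N-terminal state (``@`` = free N terminus, ``*`` = N-terminal
acetyl) and modified residues are replaced by digit tokens:

====== ==========================
token  meaning
====== ==========================
``1``  oxidized methionine
``2``  phospho-serine
``3``  phospho-threonine
``4``  phospho-tyrosine
====== ==========================

``"@A2DK"`` therefore denotes the peptide ``ASDK`` carrying a single
phosphate on Ser2.  The ion model consumes the token sequence
``[x0, x1..xn, +q]`` (charge appended); the retention-time model consumes
``[x0, x1..xn]`` without a charge token.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "PHOSPHO",
    "OXIDATION",
    "ModifiedPeptide",
    "Precursor",
    "TokenSequence",
    "Vocabulary",
    "VOCAB",
    "PeptideError",
    "parse_compact",
    "format_compact",
    "format_library_text",
    "encode_ion_input",
    "encode_rt_input",
    "read_peptide_list",
]

PHOSPHO = "phospho"
OXIDATION = "oxidation"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# digit token <-> (base residue, modification kind)
_DIGIT_TO_MOD = {
    "1": ("M", OXIDATION),
    "2": ("S", PHOSPHO),
    "3": ("T", PHOSPHO),
    "4": ("Y", PHOSPHO),
}
_MOD_TO_DIGIT = {base_mod: digit for digit, base_mod in _DIGIT_TO_MOD.items()}

#: residues a phosphate may sit on
PHOSPHO_RESIDUES = frozenset("STY")

DEFAULT_MIN_LEN = 7
DEFAULT_MAX_LEN = 50
DEFAULT_CHARGES = frozenset(range(1, 7))


class PeptideError(ValueError):
    """Raised on malformed or chemically inconsistent peptide input."""


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide with per-residue modification state.

    Parameters
    ----------
    residues : str
        Uppercase one-letter amino-acid string.
    mods : dict
        Map of 1-based residue position to modification kind
        (:data:`PHOSPHO` or :data:`OXIDATION`).
    nterm_acetyl : bool
        Whether the protein/peptide N terminus carries an acetyl group.
    """

    residues: str
    mods: dict = field(default_factory=dict)
    nterm_acetyl: bool = False

    def __post_init__(self):
        object.__setattr__(self, "mods", dict(self.mods))

    def __hash__(self):
        return hash((self.residues, tuple(sorted(self.mods.items())), self.nterm_acetyl))

    def __eq__(self, other):
        if not isinstance(other, ModifiedPeptide):
            return NotImplemented
        return (
            self.residues == other.residues
            and self.mods == other.mods
            and self.nterm_acetyl == other.nterm_acetyl
        )

    def __len__(self):
        return len(self.residues)

    @property
    def n_phospho(self) -> int:
        return sum(1 for kind in self.mods.values() if kind == PHOSPHO)

    def phospho_positions(self) -> list[int]:
        return sorted(p for p, kind in self.mods.items() if kind == PHOSPHO)

    def validate(self, min_len: int = DEFAULT_MIN_LEN, max_len: int = DEFAULT_MAX_LEN):
        """Check chemical and length invariants; raise :class:`PeptideError`."""
        n = len(self.residues)
        for aa in self.residues:
            if aa not in AMINO_ACIDS:
                raise PeptideError(f"unknown residue {aa!r} in {self.residues}")
        if not min_len <= n <= max_len:
            raise PeptideError(
                f"peptide length {n} outside [{min_len}, {max_len}]: {self.residues}"
            )
        for pos, kind in self.mods.items():
            if not 1 <= pos <= n:
                raise PeptideError(f"modification position {pos} outside 1..{n}")
            aa = self.residues[pos - 1]
            if kind == PHOSPHO and aa not in PHOSPHO_RESIDUES:
                raise PeptideError(f"phospho on {aa} at position {pos} (S/T/Y required)")
            if kind == OXIDATION and aa != "M":
                raise PeptideError(f"oxidation on {aa} at position {pos} (M required)")
            if kind not in (PHOSPHO, OXIDATION):
                raise PeptideError(f"unknown modification kind {kind!r}")
        return self


@dataclass(frozen=True)
class Precursor:
    """A modified peptide together with its precursor charge state."""

    peptide: ModifiedPeptide
    charge: int

    def __post_init__(self):
        if self.charge < 1:
            raise PeptideError(f"precursor charge must be >= 1, got {self.charge}")

    @property
    def key(self) -> tuple[str, int]:
        """(compact modified sequence, charge) — the library key."""
        return (format_compact(self.peptide), self.charge)


class Vocabulary:
    """Fixed token-id assignment shared by all models and checkpoints.

    Order: the 20 amino acids alphabetically, digits '1'-'4', '*', '@',
    charge tokens '+1'..'+6', then the pad token.  The order is frozen so
    that stored model weights remain portable.
    """

    def __init__(self, max_charge: int = 6):
        tokens = list(AMINO_ACIDS) + ["1", "2", "3", "4", "*", "@"]
        self.charge_offset = len(tokens)
        tokens += [f"+{q}" for q in range(1, max_charge + 1)]
        tokens.append("<pad>")
        self.tokens = tokens
        self.index = {t: i for i, t in enumerate(tokens)}
        self.max_charge = max_charge

    def __len__(self):
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return len(self.tokens) - 1

    def id_of(self, token: str) -> int:
        return self.index[token]

    def charge_id(self, q: int) -> int:
        if not 1 <= q <= self.max_charge:
            raise PeptideError(f"charge {q} outside 1..{self.max_charge}")
        return self.index[f"+{q}"]

    def decode(self, token_id: int) -> str:
        return self.tokens[token_id]


#: module-level default vocabulary
VOCAB = Vocabulary()


@dataclass(frozen=True)
class TokenSequence:
    """Integer token ids for one peptide, plus the charge id for ion input."""

    ids: tuple
    has_charge: bool

    def __len__(self):
        return len(self.ids)


def parse_compact(
    text: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> ModifiedPeptide:
    """Parse a compact token string into a validated :class:`ModifiedPeptide`.

    ``"@A2DK"`` -> ASDK with phospho at position 2; ``"*1PEPTIDEK"`` ->
    MPEPTIDEK with oxidized Met1 and an N-terminal acetyl.
    """
    if not text or text[0] not in "*@":
        raise PeptideError(f"compact string must start with '*' or '@': {text!r}")
    nterm_acetyl = text[0] == "*"
    residues = []
    mods = {}
    for ch in text[1:]:
        if ch in AMINO_ACIDS:
            residues.append(ch)
        elif ch in _DIGIT_TO_MOD:
            base, kind = _DIGIT_TO_MOD[ch]
            residues.append(base)
            mods[len(residues)] = kind
        else:
            raise PeptideError(f"unknown token {ch!r} in {text!r}")
    peptide = ModifiedPeptide("".join(residues), mods, nterm_acetyl)
    return peptide.validate(min_len=min_len, max_len=max_len)


def format_compact(p: ModifiedPeptide) -> str:
    """Inverse of :func:`parse_compact`."""
    out = ["*" if p.nterm_acetyl else "@"]
    for i, aa in enumerate(p.residues, start=1):
        kind = p.mods.get(i)
        out.append(_MOD_TO_DIGIT[(aa, kind)] if kind else aa)
    return "".join(out)


_BRACKET_LABEL = {
    PHOSPHO: "[Phospho (STY)]",
    OXIDATION: "[Oxidation (M)]",
}


def format_library_text(p: ModifiedPeptide, dialect: str = "bracket") -> str:
    """Render a peptide in a spectral-library text dialect.

    ``bracket`` produces Spectronaut-style strings such as
    ``_AS[Phospho (STY)]DK_``; ``compact`` is the inverse of
    :func:`parse_compact`.
    """
    if dialect == "compact":
        return format_compact(p)
    if dialect != "bracket":
        raise PeptideError(f"unknown dialect {dialect!r}")
    parts = ["_"]
    if p.nterm_acetyl:
        parts.append("[Acetyl (Protein N-term)]")
    for i, aa in enumerate(p.residues, start=1):
        parts.append(aa)
        kind = p.mods.get(i)
        if kind:
            parts.append(_BRACKET_LABEL[kind])
    parts.append("_")
    return "".join(parts)


def parse_library_text(text: str) -> ModifiedPeptide:
    """Parse a bracket-dialect modified sequence back into a peptide."""
    s = text.strip()
    if s.startswith("_") and s.endswith("_"):
        s = s[1:-1]
    nterm_acetyl = False
    if s.startswith("[Acetyl (Protein N-term)]"):
        nterm_acetyl = True
        s = s[len("[Acetyl (Protein N-term)]"):]
    residues = []
    mods = {}
    i = 0
    while i < len(s):
        ch = s[i]
        if ch == "[":
            end = s.find("]", i)
            if end < 0:
                raise PeptideError(f"unterminated bracket in {text!r}")
            label = s[i : end + 1]
            kind = {v: k for k, v in _BRACKET_LABEL.items()}.get(label)
            if kind is None:
                raise PeptideError(f"unknown modification label {label!r}")
            if not residues:
                raise PeptideError(f"modification before any residue in {text!r}")
            mods[len(residues)] = kind
            i = end + 1
        else:
            if ch not in AMINO_ACIDS:
                raise PeptideError(f"unknown residue {ch!r} in {text!r}")
            residues.append(ch)
            i += 1
    peptide = ModifiedPeptide("".join(residues), mods, nterm_acetyl)
    # library text may legitimately carry short peptides; validate chemistry only
    return peptide.validate(min_len=1, max_len=10**9)


def encode_ion_input(
    p: ModifiedPeptide, charge: int, vocab: Vocabulary = VOCAB
) -> TokenSequence:
    """Encode ``[x0, x1..xn, +q]`` for the fragment-intensity model."""
    ids = [vocab.id_of("*" if p.nterm_acetyl else "@")]
    ids.extend(_residue_ids(p, vocab))
    ids.append(vocab.charge_id(charge))
    return TokenSequence(tuple(ids), has_charge=True)


def encode_rt_input(p: ModifiedPeptide, vocab: Vocabulary = VOCAB) -> TokenSequence:
    """Encode ``[x0, x1..xn]`` (no charge token) for the iRT model."""
    ids = [vocab.id_of("*" if p.nterm_acetyl else "@")]
    ids.extend(_residue_ids(p, vocab))
    return TokenSequence(tuple(ids), has_charge=False)


def _residue_ids(p: ModifiedPeptide, vocab: Vocabulary):
    for i, aa in enumerate(p.residues, start=1):
        kind = p.mods.get(i)
        token = _MOD_TO_DIGIT[(aa, kind)] if kind else aa
        yield vocab.id_of(token)


def read_peptide_list(path, default_charge: int = 2, **validate_kw) -> list[Precursor]:
    """Read precursors from plain text or TSV.

    Plain text: one compact string per line, optional tab-separated charge.
    TSV with a header containing ``ModifiedPeptide`` and ``PrecursorCharge``
    columns is also accepted (compact or bracket dialect).
    """
    precursors = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return precursors
    header = lines[0].split("\t")
    if "ModifiedPeptide" in header:
        seq_col = header.index("ModifiedPeptide")
        chg_col = header.index("PrecursorCharge") if "PrecursorCharge" in header else None
        for ln in lines[1:]:
            fields = ln.split("\t")
            text = fields[seq_col]
            pep = (
                parse_compact(text, **validate_kw)
                if text[0] in "*@"
                else parse_library_text(text)
            )
            q = int(fields[chg_col]) if chg_col is not None else default_charge
            precursors.append(Precursor(pep, q))
    else:
        for ln in lines:
            fields = ln.split("\t")
            pep = parse_compact(fields[0], **validate_kw)
            q = int(fields[1]) if len(fields) > 1 else default_charge
            precursors.append(Precursor(pep, q))
    return precursors


def with_mods_on(p: ModifiedPeptide, positions, kind=PHOSPHO) -> ModifiedPeptide:
    """Return a copy of ``p`` with ``kind`` added at the given positions."""
    mods = dict(p.mods)
    for pos in positions:
        mods[pos] = kind
    return replace(p, mods=mods)
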
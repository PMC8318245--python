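"""Secondary-structure code sets and the mappings between them.

Two alphabets are used throughout secondary structure prediction work:
the three-state set {H, E, C} (helix, strand, coil) and the DSSP
eight-state set {G, H, I, E, B, T, S, C}.  Every other module in this
package is parameterized by an :class:`SSEAlphabet`, so user-defined
code sets (e.g. larger structural alphabets) can be registered from a
config file without code changes.

The gap character is fixed as ``'-'`` across the codebase and is never
a member of any alphabet.  Code comparison is case-sensitive; readers
upper-case their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import InvalidCodeError, ParameterError

GAP = "-"

#: The 20 standard amino-acid one-letter codes, alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SSEAlphabet:
    """A named, ordered set of single-character structure codes."""

    name: str
    codes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        codes = tuple(self.codes)
        object.__setattr__(self, "codes", codes)
        if len(set(codes)) != len(codes):
            raise ParameterError(f"alphabet {self.name!r} has duplicate codes")
        for c in codes:
            if len(c) != 1:
                raise ParameterError(f"alphabet code {c!r} is not a single character")
            if c == GAP:
                raise ParameterError("the gap character '-' cannot be an alphabet code")

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        try:
            return self.codes.index(code)
        except ValueError:
            raise InvalidCodeError(
                f"code {code!r} is not in alphabet {self.name!r}"
            ) from None

    def validate(self, s: str, where: str = "string") -> None:
        """Raise :class:`InvalidCodeError` if ``s`` has a non-gap, non-alphabet char.

        Error messages use 1-based positions.
        """
        for i, ch in enumerate(s):
            if ch != GAP and ch not in self.codes:
                raise InvalidCodeError(
                    f"invalid code {ch!r} at position {i + 1} of {where} "
                    f"(alphabet {self.name!r})"
                )


@dataclass(frozen=True)
class AlphabetReduction:
    """A total mapping from one alphabet's codes onto another's."""

    source: SSEAlphabet
    target: SSEAlphabet
    mapping: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if set(self.mapping) != set(self.source.codes):
            raise ParameterError("reduction mapping must cover every source code exactly")
        if not set(self.mapping.values()) <= set(self.target.codes):
            raise ParameterError("reduction maps onto codes outside the target alphabet")
        if set(self.mapping.values()) != set(self.target.codes):
            raise ParameterError("every target code must be hit by at least one source code")


Q3 = SSEAlphabet("q3", ("H", "E", "C"), "three-state: helix, strand, coil")
DSSP8 = SSEAlphabet(
    "dssp8",
    ("G", "H", "I", "E", "B", "T", "S", "C"),
    "DSSP eight-state secondary structure codes",
)
#: Amino-acid alphabet; lets the profile machinery build classic AA-PSSMs.
AA20 = SSEAlphabet("aa20", tuple(AMINO_ACIDS), "20 standard amino acids")

#: Standard reduction of DSSP codes onto three states:
#: helices (H, G, I), strands (E, B), coils (C, S, T).
DSSP8_TO_Q3 = AlphabetReduction(
    DSSP8,
    Q3,
    {"G": "H", "H": "H", "I": "H", "E": "E", "B": "E", "T": "C", "S": "C", "C": "C"},
)

IDENTITY_Q3 = AlphabetReduction(Q3, Q3, {c: c for c in Q3.codes})

_REGISTRY: dict[str, SSEAlphabet] = {}
_REDUCTIONS: dict[tuple[str, str], AlphabetReduction] = {}


def register_alphabet(alphabet: SSEAlphabet) -> SSEAlphabet:
    _REGISTRY[alphabet.name] = alphabet
    return alphabet


def register_reduction(reduction: AlphabetReduction) -> AlphabetReduction:
    _REDUCTIONS[(reduction.source.name, reduction.target.name)] = reduction
    return reduction


for _a in (Q3, DSSP8, AA20):
    register_alphabet(_a)
for _r in (DSSP8_TO_Q3, IDENTITY_Q3):
    register_reduction(_r)


def get_alphabet(name: str) -> SSEAlphabet:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ParameterError(
            f"unknown alphabet {name!r}; known: {sorted(_REGISTRY)}"
        ) from None


def get_reduction(source: str, target: str) -> AlphabetReduction:
    try:
        return _REDUCTIONS[(source, target)]
    except KeyError:
        raise ParameterError(f"no registered reduction {source!r} -> {target!r}") from None


def reduce_sse_string(s: str, reduction: AlphabetReduction) -> str:
    """Map a structure string onto the reduction's target alphabet.

    The gap character passes through unchanged; any other character
    outside the source alphabet raises :class:`InvalidCodeError` naming
    the (1-based) offending position.
    """
    out = []
    for i, ch in enumerate(s):
        if ch == GAP:
            out.append(GAP)
        elif ch in reduction.mapping:
            out.append(reduction.mapping[ch])
        else:
            raise InvalidCodeError(
                f"invalid code {ch!r} at position {i + 1}: not in alphabet "
                f"{reduction.source.name!r}"
            )
    return "".join(out)


def load_alphabet_config(path) -> SSEAlphabet:
    """Register an alphabet (and optional reduction) from a flat key-value file.

    The file is YAML with keys ``name``, ``codes`` (a string of symbols)
    and optionally ``reduce_to`` plus ``mapping`` (source char -> target
    char).  Returns the registered alphabet.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "name" not in cfg or "codes" not in cfg:
        raise ParameterError(f"alphabet config {path} must define 'name' and 'codes'")
    alphabet = SSEAlphabet(str(cfg["name"]), tuple(str(cfg["codes"])), cfg.get("description", ""))
    register_alphabet(alphabet)
    if "reduce_to" in cfg:
        target = get_alphabet(str(cfg["reduce_to"]))
        mapping = {str(k): str(v) for k, v in dict(cfg["mapping"]).items()}
        register_reduction(AlphabetReduction(alphabet, target, mapping))
    return alphabet
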
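"""Molecular descriptor computation from SMILES via pluggable backends.

The platform treats descriptor generation as a backend contract: a backend
exposes an ordered descriptor-name list and maps one SMILES string to a
fixed-length numeric vector, deterministically. Chemistry-engine backends
(RDKit when installed) plug in through the same contract as the built-in
lexical backend, which computes token-level counts by scanning the SMILES
text and therefore works without any chemistry dependency. The lexical
counts are not chemically canonical (no aromaticity perception, no implicit
hydrogens) — they are structural surrogates that exercise the full
SMILES -> feature-table path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import CONTINUOUS, META, Dataset, VariableSchema
from .exceptions import BackendMissingError


@dataclass(frozen=True)
class DescriptorBackend:
    """One descriptor engine: a name, an ordered descriptor list and a
    ``compute`` contract mapping a SMILES string to a vector of
    ``len(descriptor_names)`` floats. ``compute`` raises ``ValueError`` for
    input it rejects; callers turn that into an all-missing row."""

    name: str
    descriptor_names: tuple[str, ...]
    compute: Callable[[str], np.ndarray]


# -- built-in lexical backend -------------------------------------------------

_ORGANIC_ONE = set("BCNOPSFI")
_AROMATIC = set("bcnops")
_HALOGENS = {"F", "Cl", "Br", "I"}

LEXICAL_DESCRIPTORS = (
    "heavy_atoms",
    "carbon_count",
    "nitrogen_count",
    "oxygen_count",
    "sulfur_count",
    "halogen_count",
    "ring_count",
    "branch_count",
    "double_bond_count",
    "triple_bond_count",
    "charge_count",
    "smiles_length",
)


def _scan_smiles(s: str) -> dict[str, float]:
    """Tokenize a SMILES string and count structural tokens.

    Raises ValueError on text that is not well-formed SMILES at the lexical
    level: unknown characters, unbalanced brackets or parentheses, an
    unmatched ring-closure label, or no atoms at all.
    """
    if not s:
        raise ValueError("empty SMILES")
    counts = dict.fromkeys(LEXICAL_DESCRIPTORS, 0.0)
    counts["smiles_length"] = float(len(s))
    ring_open: dict[str, int] = {}
    depth = 0
    i = 0
    n = len(s)

    def atom(symbol: str) -> None:
        counts["heavy_atoms"] += symbol != "H"
        up = symbol.capitalize()
        if up == "C":
            counts["carbon_count"] += 1
        elif up == "N":
            counts["nitrogen_count"] += 1
        elif up == "O":
            counts["oxygen_count"] += 1
        elif up == "S":
            counts["sulfur_count"] += 1
        if symbol in _HALOGENS:
            counts["halogen_count"] += 1

    def ring_label(label: str) -> None:
        if ring_open.pop(label, None) is None:
            ring_open[label] = 1
        else:
            counts["ring_count"] += 1

    while i < n:
        ch = s[i]
        if ch == "[":
            j = s.find("]", i)
            if j < 0:
                raise ValueError("unclosed bracket atom")
            body = s[i + 1 : j]
            k = 0
            while k < len(body) and body[k].isdigit():  # isotope prefix
                k += 1
            if k < len(body) and body[k].isalpha():
                sym = body[k]
                if k + 1 < len(body) and body[k : k + 2] in ("Cl", "Br"):
                    sym = body[k : k + 2]
                atom(sym if len(sym) == 2 else sym)
            else:
                raise ValueError(f"bracket atom without element: [{body}]")
            counts["charge_count"] += body.count("+") + body.count("-")
            i = j + 1
        elif s.startswith("Cl", i) or s.startswith("Br", i):
            atom(s[i : i + 2])
            i += 2
        elif ch in _ORGANIC_ONE or ch in _AROMATIC:
            atom(ch)
            i += 1
        elif ch.isdigit():
            ring_label(ch)
            i += 1
        elif ch == "%":
            if i + 2 >= n or not s[i + 1 : i + 3].isdigit():
                raise ValueError("malformed %nn ring label")
            ring_label(s[i + 1 : i + 3])
            i += 3
        elif ch == "(":
            counts["branch_count"] += 1
            depth += 1
            i += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError("unbalanced parentheses")
            i += 1
        elif ch == "=":
            counts["double_bond_count"] += 1
            i += 1
        elif ch == "#":
            counts["triple_bond_count"] += 1
            i += 1
        elif ch in "-+/\\.@:~":
            i += 1  # bonds, chirality, separators: no count kept
        else:
            raise ValueError(f"unexpected character {ch!r} in SMILES")
    if depth != 0:
        raise ValueError("unbalanced parentheses")
    if ring_open:
        raise ValueError(f"unmatched ring label(s): {sorted(ring_open)}")
    if counts["heavy_atoms"] == 0:
        raise ValueError("no atoms found")
    return counts


def _lexical_compute(smiles: str) -> np.ndarray:
    counts = _scan_smiles(smiles)
    return np.array([counts[name] for name in LEXICAL_DESCRIPTORS], dtype=float)


def builtin_backend() -> DescriptorBackend:
    """The dependency-free token-count backend (see module docstring)."""
    return DescriptorBackend("builtin", LEXICAL_DESCRIPTORS, _lexical_compute)


def rdkit_backend() -> DescriptorBackend:
    """A small physicochemical descriptor set via RDKit, when installed."""
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise BackendMissingError("descriptor backend 'rdkit' is not installed") from exc
    RDLogger.DisableLog("rdApp.error")
    names = (
        "MolWt",
        "HeavyAtomCount",
        "RingCount",
        "TPSA",
        "MolLogP",
        "NumHAcceptors",
        "NumHDonors",
        "NumRotatableBonds",
    )

    def compute(smiles: str) -> np.ndarray:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"RDKit rejected SMILES {smiles!r}")
        return np.array(
            [
                Descriptors.MolWt(mol),
                mol.GetNumHeavyAtoms(),
                rdMolDescriptors.CalcNumRings(mol),
                rdMolDescriptors.CalcTPSA(mol),
                Crippen.MolLogP(mol),
                Lipinski.NumHAcceptors(mol),
                Lipinski.NumHDonors(mol),
                Lipinski.NumRotatableBonds(mol),
            ],
            dtype=float,
        )

    return DescriptorBackend("rdkit", names, compute)


_BACKENDS: dict[str, Callable[[], DescriptorBackend]] = {
    "builtin": builtin_backend,
    "rdkit": rdkit_backend,
}


def get_backend(name: str) -> DescriptorBackend:
    try:
        factory = _BACKENDS[name]
    except KeyError:
        raise BackendMissingError(f"unknown descriptor backend {name!r}") from None
    return factory()


# -- SMILES -> feature table --------------------------------------------------


def compute_descriptors(
    smiles: Sequence[str],
    backend: DescriptorBackend | str = "builtin",
    smiles_column: str = "SMILES",
) -> tuple[Dataset, list[str]]:
    """Turn a SMILES list into a descriptor table, one row per input.

    Rows the backend rejects are kept (row alignment with any response is
    preserved) with all features missing; the second return value reports
    one entry per failure.
    """
    if len(smiles) == 0:
        raise ValueError("empty SMILES list")
    if isinstance(backend, str):
        backend = get_backend(backend)
    rows = np.full((len(smiles), len(backend.descriptor_names)), np.nan)
    report: list[str] = []
    for i, smi in enumerate(smiles):
        try:
            rows[i] = backend.compute(str(smi))
        except ValueError as exc:
            report.append(f"row {i}: could not parse {smi!r}: {exc}")
    schema = [VariableSchema(smiles_column, CONTINUOUS, role=META)]
    schema += [VariableSchema(nm) for nm in backend.descriptor_names]
    df = pd.DataFrame(rows, columns=list(backend.descriptor_names))
    df.insert(0, smiles_column, list(smiles))
    return Dataset(schema, df), report


def read_smi(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a .smi file: one SMILES per line, optional whitespace-separated ID.

    Returns (smiles, ids); an absent ID defaults to the 1-based line number.
    """
    smiles, ids = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smiles.append(parts[0])
        ids.append(parts[1].strip() if len(parts) > 1 else str(lineno))
    return smiles, ids
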
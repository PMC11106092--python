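"""FASTA input with residue validation."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Tuple, Union

from pyteomics import fasta as _fasta

from .digest import validate_sequence
from .residues import AMBIGUOUS_RESIDUES


def read_fasta(
    path: Union[str, Path], allow_ambiguous: bool = False
) -> List[Tuple[str, str]]:
    """Read protein records from a FASTA file.

    Returns ``(protein_id, sequence)`` pairs in file order, where the id is
    the first whitespace-delimited token of the header. Sequences are
    uppercased, whitespace-stripped and validated against the 20 canonical
    residues; with ``allow_ambiguous`` the codes B/Z/X pass with a warning
    (peptides containing them have no defined composition and are excluded
    from search spaces downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: List[Tuple[str, str]] = []
    with _fasta.read(str(path)) as reader:
        for description, sequence in reader:
            pid = description.split()[0] if description.split() else description
            seq = validate_sequence(sequence, record_id=pid,
                                    allow_ambiguous=allow_ambiguous)
            if allow_ambiguous and set(seq) & AMBIGUOUS_RESIDUES:
                warnings.warn(
                    f"record {pid!r} contains ambiguous residue codes",
                    stacklevel=2,
                )
            records.append((pid, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
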
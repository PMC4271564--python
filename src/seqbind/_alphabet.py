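"""Canonical amino-acid ordering shared by profiles and property scales.

All 20-dimensional vectors in this package (profile rows, property scales)
are stored in ``CANONICAL_AA`` order.  External formats use their own
layouts (PSI-BLAST PSSM columns, AAindex I-block rows) and are remapped on
parse.
"""

from __future__ import annotations

import numpy as np

#: Alphabetical one-letter order used internally everywhere.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of PSI-BLAST ASCII PSSMs; also the concatenation of the two
#: AAindex I-block rows (A R N D C Q E G H I / L K M F P S T W Y V).
PSSM_ORDER = "ARNDCQEGHILKMFPSTWYV"
AAINDEX_ORDER = PSSM_ORDER

CANONICAL_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


def reorder_to_canonical(values, source_order: str) -> np.ndarray:
    """Reorder a 20-vector (or L x 20 matrix columns) into canonical order."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[-1] != 20:
        raise ValueError(f"expected 20 amino-acid entries, got {arr.shape[-1]}")
    perm = [source_order.index(aa) for aa in CANONICAL_AA]
    return arr[..., perm]
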
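"""Residue feature encoding from evolutionary profiles and AAindex scales.

Each residue carries a 20-dimensional profile row (normalized PSI-BLAST
weighted percentages, or a pseudo-profile when no PSSM exists).  For one
amino-acid property scale ``AAP_j`` the residue's descriptor is the standard
deviation of the element-wise product ``profile_row * AAP_j`` over the 20
amino acids — a scalar that grows when the profile concentrates on residues
with extreme property values, i.e. it captures evolutionary conservation
seen through one physico-chemical lens.  A sliding window of length W stacks
these scalars for the W neighbours of the centre residue across all P
selected properties, giving a W*P feature vector (238 for W=7, P=34).

Property scales are de-redundantized by a greedy correlation filter:
scales whose Pearson correlation magnitude reaches a threshold (0.5 by
default) are "related"; scales are ranked by how many partners they have,
and taking a scale removes its partners until no related pair survives.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._alphabet import AAINDEX_ORDER, CANONICAL_AA, CANONICAL_INDEX, PSSM_ORDER, reorder_to_canonical

logger = logging.getLogger(__name__)

#: Multi-window set used for the window-combination predictor.
DEFAULT_WINDOWS: tuple[int, ...] = (5, 7, 9, 11, 17, 27, 37, 47, 57)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PropertyScale:
    """One AAindex scale: 20 values in canonical amino-acid order."""

    accession: str
    description: str
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.values) != 20:
            raise ValueError(f"{self.accession}: expected 20 values, got {len(self.values)}")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError(f"{self.accession}: non-finite value")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values)


@dataclass
class PropertySet:
    """Scales surviving the correlation filter, in deterministic order."""

    scales: list[PropertyScale]
    threshold: float
    selection_log: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scales)

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(s.accession for s in self.scales)

    @property
    def matrix(self) -> np.ndarray:
        """P x 20 array of scale values."""
        return np.stack([s.array for s in self.scales])


@dataclass
class ProfileMatrix:
    """L x 20 row-stochastic evolutionary profile in canonical order."""

    matrix: np.ndarray
    source: str = "pssm"  # "pssm" | "pseudo"
    sequence: str | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got {self.matrix.shape}")
        if (self.matrix < 0).any():
            raise ValueError("profile entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"profile row {bad} sums to {sums[bad]:.6f}, not 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class WindowSpec:
    """A single odd window length plus the multi-window set it belongs to."""

    window: int = 7
    windows: tuple[int, ...] = DEFAULT_WINDOWS

    def __post_init__(self):
        for w in (self.window, *self.windows):
            if w < 1 or w % 2 == 0:
                raise ValueError(f"window length must be odd and >= 1, got {w}")


@dataclass
class FeatureMatrix:
    """L x (W*P) windowed std features with column-layout metadata.

    Columns are window-offset-major, property-minor: column ``o*P + j`` is
    property ``j`` at window offset ``o`` (offsets run -(W-1)/2 .. +(W-1)/2).
    """

    values: np.ndarray
    window: int
    accessions: tuple[str, ...]
    padding: str = "zero"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = self.window * len(self.accessions)
        if self.values.ndim != 2 or self.values.shape[1] != expected:
            raise ValueError(
                f"feature matrix has {self.values.shape[1]} columns, expected "
                f"W*P = {self.window}*{len(self.accessions)} = {expected}"
            )

    @property
    def fingerprint(self) -> str:
        """Stable hash of the feature-space layout; must match at predict time."""
        meta = {
            "window": self.window,
            "accessions": list(self.accessions),
            "padding": self.padding,
            "layout": "offset-major",
        }
        return hashlib.md5(json.dumps(meta, sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# AAindex parsing and property selection


def parse_aaindex(text: str, na_policy: str = "drop") -> list[PropertyScale]:
    """Parse an AAindex1 flat file into PropertyScales (canonical AA order).

    Entries containing ``NA`` values are dropped (default) or mean-imputed
    (``na_policy="mean"``).
    """
    if na_policy not in ("drop", "mean"):
        raise ValueError(f"unknown NA policy {na_policy!r}")
    scales: list[PropertyScale] = []
    lines = text.splitlines()
    i = 0
    accession = ""
    description = ""
    while i < len(lines):
        line = lines[i]
        if line.startswith("H "):
            accession = line[2:].strip()
            description = ""
        elif line.startswith("D "):
            description = line[2:].strip()
        elif line.startswith("I "):
            if i + 2 >= len(lines):
                raise ValueError(f"{accession}: truncated I-block")
            raw = lines[i + 1].split() + lines[i + 2].split()
            if len(raw) != 20:
                raise ValueError(
                    f"{accession}: I-block has {len(raw)} values, expected 20"
                )
            vals: list[float] = []
            for tok in raw:
                if tok.upper() == "NA":
                    vals.append(math.nan)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        raise ValueError(f"{accession}: bad value {tok!r} in I-block") from None
            arr = np.array(vals)
            if np.isnan(arr).any():
                if na_policy == "drop":
                    logger.info("dropping %s: contains NA values", accession)
                    i += 3
                    continue
                arr = np.where(np.isnan(arr), np.nanmean(arr), arr)
            canonical = reorder_to_canonical(arr, AAINDEX_ORDER)
            scales.append(
                PropertyScale(accession=accession, description=description, values=tuple(canonical))
            )
            i += 2
        i += 1
    return scales


def select_properties(scales: Sequence[PropertyScale], threshold: float = 0.5) -> PropertySet:
    """Greedy correlation filter keeping a maximal unrelated subset.

    Two scales are related when |Pearson CC| of their 20 values >= threshold.
    Scales are ranked by descending related-partner count (ties by accession);
    repeatedly the top-ranked remaining scale is kept and its related partners
    removed.  Survivors are returned sorted by accession, which makes the
    filter idempotent.
    """
    if not scales:
        raise ValueError("select_properties requires at least one scale")
    usable = []
    for s in scales:
        if np.std(s.array) == 0:
            warnings.warn(f"dropping constant scale {s.accession} (correlation undefined)")
            continue
        usable.append(s)
    if not usable:
        raise ValueError("all scales are constant; correlation filter undefined")

    mat = np.stack([s.array for s in usable])
    cc = np.corrcoef(mat)
    related = (np.abs(cc) >= threshold) & ~np.eye(len(usable), dtype=bool)
    counts = related.sum(axis=1)

    order = sorted(range(len(usable)), key=lambda k: (-int(counts[k]), usable[k].accession))
    alive = set(range(len(usable)))
    kept: list[int] = []
    removed: dict[str, str] = {}
    for k in order:
        if k not in alive:
            continue
        kept.append(k)
        partners = set(np.flatnonzero(related[k])) & alive
        for p in partners - {k}:
            removed[usable[p].accession] = usable[k].accession
        alive -= partners
        alive.discard(k)

    survivors = sorted((usable[k] for k in kept), key=lambda s: s.accession)
    log = {
        "kept": [s.accession for s in survivors],
        "removed_by": removed,
        "related_counts": {usable[k].accession: int(counts[k]) for k in range(len(usable))},
    }
    return PropertySet(scales=survivors, threshold=threshold, selection_log=log)


# ---------------------------------------------------------------------------
# profiles


def _parse_header_order(lines: list[str]) -> str:
    for line in lines[:6]:
        toks = line.split()
        if len(toks) >= 40 and all(t in CANONICAL_AA for t in toks[:40]):
            return "".join(toks[:20])
    return PSSM_ORDER


def parse_pssm(text: str, expected_length: int | None = None) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM into a row-stochastic profile.

    Uses the weighted-percentage block (columns 21-40) divided by 100.
    All-zero percentage rows (no alignment information) fall back to the
    one-hot row of the query residue.
    """
    lines = text.splitlines()
    order = _parse_header_order(lines)
    rows: list[np.ndarray] = []
    seq: list[str] = []
    for lineno, line in enumerate(lines, start=1):
        toks = line.split()
        if len(toks) < 42:
            continue
        try:
            int(toks[0])
        except ValueError:
            continue
        if toks[1].upper() not in CANONICAL_AA and toks[1].upper() != "X":
            continue
        try:
            pcts = np.array([float(t) for t in toks[22:42]])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric PSSM cell ({exc})") from None
        seq.append(toks[1].upper())
        rows.append(pcts)
    if not rows:
        raise ValueError("no PSSM data rows found")
    if expected_length is not None and len(rows) != expected_length:
        raise ValueError(
            f"PSSM has {len(rows)} rows but sequence declares {expected_length}"
        )
    mat = np.stack(rows) / 100.0
    mat = reorder_to_canonical(mat, order)
    for i, row in enumerate(mat):
        if row.sum() == 0:
            aa = seq[i]
            if aa in CANONICAL_INDEX:
                mat[i, CANONICAL_INDEX[aa]] = 1.0
            else:  # X with no information: uniform
                mat[i, :] = 1.0 / 20.0
        else:
            mat[i] = row / row.sum()
    return ProfileMatrix(matrix=mat, source="pssm", sequence="".join(seq))


def write_pssm(profile: ProfileMatrix, path, decimals: int = 0) -> None:
    """Write a profile in the two-block PSI-BLAST ASCII dialect.

    Log-odds are synthesized as round(10*log2(p/0.05)); percentages are
    written with ``decimals`` decimal places (0 mimics real PSI-BLAST
    integer quantization).
    """
    seq = profile.sequence or "X" * len(profile)
    perm = [CANONICAL_AA.index(aa) for aa in PSSM_ORDER]
    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    cols = " ".join(f"{aa:>3}" for aa in PSSM_ORDER)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(f"         {cols}  {cols}\n")
        for i, row in enumerate(profile.matrix):
            ext = row[perm]
            with np.errstate(divide="ignore"):
                lod = np.where(ext > 0, np.round(10 * np.log2(np.maximum(ext, 1e-9) / 0.05)), -10)
            lod_s = " ".join(f"{int(v):>3d}" for v in lod)
            if decimals == 0:
                # largest-remainder rounding so integer percentages sum to 100,
                # keeping per-entry quantization error below 0.01
                scaled = 100 * ext
                ints = np.floor(scaled).astype(int)
                short = 100 - int(ints.sum())
                if short > 0:
                    frac_order = np.argsort(-(scaled - ints))
                    ints[frac_order[:short]] += 1
                pct_s = " ".join(f"{v:>3d}" for v in ints)
            else:
                pct_s = " ".join(f"{100 * v:.{decimals}f}" for v in ext)
            fh.write(f"{i + 1:>5d} {seq[i]}  {lod_s}  {pct_s}  0.00 0.00\n")


def pseudo_profile(sequence: str, eps: float = 0.05) -> ProfileMatrix:
    """Sequence-only fallback profile: (1-eps) on the observed residue,
    eps/19 elsewhere; 'X' gives a uniform row."""
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    mat = np.full((L, 20), 0.0)
    for i, aa in enumerate(sequence.upper()):
        if aa == "X":
            mat[i, :] = 1.0 / 20.0
        elif aa in CANONICAL_INDEX:
            mat[i, :] = eps / 19.0
            mat[i, CANONICAL_INDEX[aa]] = 1.0 - eps
        else:
            raise ValueError(f"unknown residue letter {aa!r} at position {i}")
    return ProfileMatrix(matrix=mat, source="pseudo", sequence=sequence.upper())


# ---------------------------------------------------------------------------
# encoding


def property_std_profile(
    profile: ProfileMatrix, properties: PropertySet, ddof: int = 0
) -> np.ndarray:
    """L x P matrix of per-residue, per-property descriptors.

    Entry (k, j) is the standard deviation over the 20 amino acids of
    ``profile_row_k * scale_j`` (population form, divisor 20, by default).
    """
    prods = profile.matrix[:, None, :] * properties.matrix[None, :, :]
    return prods.std(axis=2, ddof=ddof)


def encode_chain(
    profile: ProfileMatrix,
    properties: PropertySet,
    window: int | WindowSpec = 7,
    padding: str = "zero",
    ddof: int = 0,
) -> FeatureMatrix:
    """Windowed std-feature encoding of one chain.

    Positions outside the chain contribute 0 under ``padding="zero"`` (the
    "no information" value for a non-negative std feature) or replicate the
    terminal residue under ``padding="edge"``.
    """
    w = window.window if isinstance(window, WindowSpec) else int(window)
    if w < 1 or w % 2 == 0:
        raise ValueError(f"window length must be odd and >= 1, got {w}")
    if padding not in ("zero", "edge"):
        raise ValueError(f"unknown padding {padding!r}")
    if len(properties) < 1:
        raise ValueError("need at least one property scale")

    S = property_std_profile(profile, properties, ddof=ddof)  # L x P
    L, P = S.shape
    half = w // 2
    blocks = []
    for offset in range(-half, half + 1):
        if padding == "zero":
            block = np.zeros_like(S)
            lo, hi = max(0, -offset), min(L, L - offset)
            block[lo:hi] = S[lo + offset : hi + offset]
        else:
            idx = np.clip(np.arange(L) + offset, 0, L - 1)
            block = S[idx]
        blocks.append(block)
    values = np.concatenate(blocks, axis=1)
    return FeatureMatrix(
        values=values, window=w, accessions=properties.accessions, padding=padding
    )


def write_property_set(properties: PropertySet, path) -> None:
    payload = {
        "threshold": properties.threshold,
        "scales": [
            {"accession": s.accession, "description": s.description, "values": list(s.values)}
            for s in properties.scales
        ],
        "selection_log": properties.selection_log,
        "aa_order": CANONICAL_AA,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_property_set(path) -> PropertySet:
    with open(path) as fh:
        payload = json.load(fh)
    scales = [
        PropertyScale(s["accession"], s.get("description", ""), tuple(s["values"]))
        for s in payload["scales"]
    ]
    return PropertySet(
        scales=scales,
        threshold=payload["threshold"],
        selection_log=payload.get("selection_log", {}),
    )
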
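"""Combinatorial split-pool barcodes: whitelist design and demultiplexing.

Cells are indexed by two rounds of barcodes (a 6 bp plate index and an
8 bp PCR index by default), giving ``|round1| x |round2|`` combinations.
Because the enrichment chemistry methylates GATC, whitelist codes must
avoid that substring; codes within a round keep a minimum pairwise
Hamming distance so that sequencing errors up to ``max_mismatch`` decode
uniquely (ties are never broken arbitrarily — they are unassigned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import MOTIF

_BASES = ("A", "C", "G", "T")
UNASSIGNED = -1


class CapacityError(ValueError):
    """Whitelist request infeasible at the given length/distance."""


@dataclass(frozen=True)
class BarcodeScheme:
    round1_codes: tuple[str, ...]
    round2_codes: tuple[str, ...]
    max_mismatch: int = 1

    def __post_init__(self):
        for codes in (self.round1_codes, self.round2_codes):
            if len({len(c) for c in codes}) > 1:
                raise ValueError("codes within a round must share one length")
            if any(MOTIF in c for c in codes):
                raise ValueError(f"codes must not contain {MOTIF}")


def combination_capacity(scheme: BarcodeScheme) -> int:
    """Number of distinct (round1, round2) cell identifiers."""
    return len(scheme.round1_codes) * len(scheme.round2_codes)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def generate_whitelist(
    n_codes: int,
    code_length: int,
    min_distance: int = 2,
    rng_seed: int = 0,
    max_attempts: int = 200_000,
) -> list[str]:
    """Rejection-sample GATC-free codes with pairwise Hamming >= min_distance.

    Raises :class:`CapacityError` when the request cannot be met within the
    attempt budget (or is provably impossible by the Singleton bound
    ``4^(L - d + 1)``).
    """
    if n_codes < 1 or code_length < 1 or min_distance < 1:
        raise ValueError("n_codes, code_length and min_distance must be positive")
    singleton = 4 ** max(0, code_length - min_distance + 1)
    if n_codes > singleton:
        raise CapacityError(
            f"{n_codes} codes of length {code_length} at distance {min_distance} "
            f"exceed the Singleton bound ({singleton})"
        )
    rng = np.random.default_rng(rng_seed)
    codes: list[str] = []
    arr = np.empty((0, code_length), dtype=np.int8)
    attempts = 0
    while len(codes) < n_codes:
        attempts += 1
        if attempts > max_attempts:
            raise CapacityError(
                f"could not place {n_codes} codes of length {code_length} at "
                f"pairwise distance {min_distance} in {max_attempts} attempts "
                f"(reached {len(codes)}); the distance constraint is binding"
            )
        cand = rng.integers(0, 4, size=code_length, dtype=np.int8)
        code = "".join(_BASES[b] for b in cand)
        if MOTIF in code:
            continue
        if arr.size and int((arr != cand).sum(axis=1).min()) < min_distance:
            continue
        codes.append(code)
        arr = np.vstack([arr, cand])
    return codes


def assign_barcode(observed: str, codes: list[str] | tuple[str, ...], max_mismatch: int = 1) -> int:
    """Index of the unique code within ``max_mismatch`` of ``observed``.

    Returns :data:`UNASSIGNED` when no code qualifies or when two codes tie
    at the minimal distance (mis-assignment would inflate collision-rate
    estimates, so ties are dropped rather than broken).
    """
    if len(observed) != len(codes[0]):
        raise ValueError("observed sequence length differs from code length")
    dists = [hamming(observed, c) for c in codes]
    best = min(dists)
    if best > max_mismatch or dists.count(best) > 1:
        return UNASSIGNED
    return dists.index(best)


def _encode(codes) -> np.ndarray:
    lut = np.zeros(128, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    return np.vstack([lut[np.frombuffer(c.encode(), dtype=np.uint8)] for c in codes])


def _assign_many(observed: pd.Series, codes, max_mismatch: int) -> np.ndarray:
    """Vectorized nearest-unique-code assignment for a column of sequences."""
    uniq, inverse = np.unique(observed.to_numpy(dtype=object), return_inverse=True)
    code_arr = _encode(codes)
    out = np.full(len(uniq), UNASSIGNED, dtype=np.int64)
    for k, seq in enumerate(uniq):
        if len(seq) != code_arr.shape[1]:
            continue  # malformed row: left unassigned, counted by caller
        obs = _encode([seq])[0]
        d = (code_arr != obs).sum(axis=1)
        best = int(d.min())
        if best <= max_mismatch and int((d == best).sum()) == 1:
            out[k] = int(d.argmin())
    return out[inverse]


def demultiplex(
    pairs: pd.DataFrame, scheme: BarcodeScheme,
    bc1_col: str = "bc1_seq", bc2_col: str = "bc2_seq",
) -> tuple[pd.DataFrame, int]:
    """Assign each pair to a (round1, round2) cell identifier.

    Returns the assigned subset (with ``bc1_idx``/``bc2_idx``/``cell_id``
    columns) and the count of unassigned pairs; assigned + unassigned
    equals the input row count.
    """
    i1 = _assign_many(pairs[bc1_col], scheme.round1_codes, scheme.max_mismatch)
    i2 = _assign_many(pairs[bc2_col], scheme.round2_codes, scheme.max_mismatch)
    ok = (i1 != UNASSIGNED) & (i2 != UNASSIGNED)
    out = pairs.loc[ok].copy()
    out["bc1_idx"] = i1[ok]
    out["bc2_idx"] = i2[ok]
    out["cell_id"] = [f"{a}-{b}" for a, b in zip(i1[ok], i2[ok])]
    return out, int((~ok).sum())


def attach_barcodes(
    pairs: pd.DataFrame, truth: pd.DataFrame, scheme: BarcodeScheme,
    error_rate: float = 0.0, rng_seed: int = 0,
) -> pd.DataFrame:
    """Emit raw barcode sequence columns for each pair from the planted
    (bc1_idx, bc2_idx) of its barcode, with optional per-base errors
    (demultiplexer stress-testing)."""
    rng = np.random.default_rng(rng_seed)
    lookup = truth.set_index("cell_id")[["bc1_idx", "bc2_idx"]]
    idx = lookup.loc[pairs["cell_id"]].to_numpy()
    out = pairs.copy()
    for col, codes, which in (("bc1_seq", scheme.round1_codes, 0),
                              ("bc2_seq", scheme.round2_codes, 1)):
        seqs = np.asarray(codes, dtype=object)[idx[:, which] % len(codes)]
        if error_rate > 0:
            lut = np.zeros(128, dtype=np.int8)
            for i, b in enumerate(_BASES):
                lut[ord(b)] = i
            mat = lut[np.vstack([np.frombuffer(s.encode(), dtype=np.uint8) for s in seqs])]
            hit = rng.random(mat.shape) < error_rate
            # a hit always substitutes a *different* base
            mat = (mat + hit * rng.integers(1, 4, mat.shape)) % 4
            base_bytes = np.frombuffer("".join(_BASES).encode(), dtype=np.uint8)
            seqs = np.array([bytes(base_bytes[row]).decode() for row in mat], dtype=object)
        out[col] = seqs
    return out


def write_whitelist(codes, path) -> None:
    pd.DataFrame({"index": range(len(codes)), "sequence": codes}).to_csv(
        path, sep="\t", index=False, header=False)


def read_whitelist(path) -> list[str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["index", "sequence"])
    return list(df["sequence"])
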
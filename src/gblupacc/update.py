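"""Incremental accuracy for new genotyped individuals.

The expensive object in the classic path is the inverse of the full
coefficient matrix.  Rewriting C^-1 with the Woodbury identity shows that
the only large matrix that must ever be inverted is

    M = G_pp + alpha * (Z'Z)_pp^-1

over the core (reference) individuals, all of whom are phenotyped so
(Z'Z)_pp is diagonal and invertible.  For a single new individual q with
relationship vector g_pq to the core, self-relationship g_qq and record
count z_qq, the prediction-error diagonal element reduces to scalar algebra
on the Schur residual

    k = g_qq - g_pq' M^-1 g_pq

    c^qq = k / (k * z_qq + alpha)      (z_qq >= 1, with phenotype)
    c^qq = k / alpha                   (z_qq  = 0, the z -> 0 limit)

Each query is one symmetric matrix-vector product in the core dimension.
Growing the reference by one phenotyped animal is the Schur-complement
block-inverse update of M^-1 (rank-one, no refactorization), and M^-1 can
be persisted to a binary state file between evaluation runs.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from .classic import AccuracyResult, ModelParams, henderson_scores
from .exceptions import (
    DimensionError,
    InconsistentInputsError,
    NotPositiveDefiniteError,
    StateFormatError,
    StateIntegrityError,
    ValidationError,
    WrongOperationError,
)
from .grm import GRM
from .simulate import RecordCounts

__all__ = [
    "ReferenceState",
    "NewIndividual",
    "SchurUpdateParts",
    "build_reference",
    "cqq_with_phenotype",
    "cqq_without_phenotype",
    "score_new_individual",
    "update_reference",
    "save_state",
    "load_state",
]

STATE_MAGIC = b"MINV"
STATE_VERSION = 1
_FLAG_COMPRESSED = 0x01
_FLAG_HAS_DIAG = 0x02


@dataclass
class ReferenceState:
    """The reusable core of an evaluation: ids, alpha and M^-1.

    ``minv`` is stored explicitly (not as a factor) so that a c^qq query is
    a single symmetric matrix-vector product.  ``core_grm_diag`` keeps the
    g_ii of core animals for reporting; it is optional and not needed for
    scoring new individuals.
    """

    core_ids: tuple[str, ...]
    alpha: float
    minv: np.ndarray
    core_grm_diag: np.ndarray | None = None
    version: int = STATE_VERSION

    def __post_init__(self) -> None:
        self.core_ids = tuple(str(i) for i in self.core_ids)
        self.minv = np.asarray(self.minv, dtype=float)
        p = len(self.core_ids)
        if len(set(self.core_ids)) != p:
            raise ValidationError("duplicate core ids")
        if self.minv.shape != (p, p):
            raise DimensionError(
                f"minv must be {p}x{p} to match core_ids, got {self.minv.shape}"
            )
        self.minv = (self.minv + self.minv.T) / 2.0
        if self.core_grm_diag is not None:
            self.core_grm_diag = np.asarray(self.core_grm_diag, dtype=float)
            if self.core_grm_diag.shape != (p,):
                raise DimensionError("core_grm_diag length must equal core size")

    @property
    def n_core(self) -> int:
        return len(self.core_ids)


@dataclass
class NewIndividual:
    """A genotyped individual to score against (or add to) the core."""

    id: str
    g_pq: np.ndarray
    g_qq: float
    z_qq: int = 0

    def __post_init__(self) -> None:
        self.id = str(self.id)
        self.g_pq = np.asarray(self.g_pq, dtype=float).ravel()
        self.g_qq = float(self.g_qq)
        self.z_qq = int(self.z_qq)
        if self.g_qq <= 0:
            raise ValidationError(f"g_qq must be positive, got {self.g_qq}")
        if self.z_qq < 0:
            raise ValidationError(f"z_qq must be non-negative, got {self.z_qq}")


@dataclass(frozen=True)
class SchurUpdateParts:
    """Intermediates of the scalar Schur update.

    k  = g_qq - g_pq' M^-1 g_pq        (genomic Schur residual)
    s  = k + alpha / z_qq              (full Schur complement; z_qq >= 1)
    sn2 = -M^-1 g_pq / s,  sn4 = 1/s   (new blocks of the grown M^-1)
    """

    k: float
    s: float | None
    sn2: np.ndarray | None
    sn4: float | None


def _check_dims(state: ReferenceState, ind: NewIndividual) -> None:
    if ind.g_pq.shape[0] != state.n_core:
        raise DimensionError(
            f"g_pq has length {ind.g_pq.shape[0]} but the core has "
            f"{state.n_core} individuals"
        )


def _schur_residual(state: ReferenceState, ind: NewIndividual) -> tuple[float, np.ndarray]:
    """k = g_qq - g_pq' M^-1 g_pq, plus the reusable vector M^-1 g_pq."""
    _check_dims(state, ind)
    v = state.minv @ ind.g_pq
    k = float(ind.g_qq - ind.g_pq @ v)
    if k <= 0:
        raise InconsistentInputsError(
            f"Schur residual k = {k} <= 0 for individual {ind.id!r}: the "
            "augmented relationship matrix would not be positive definite"
        )
    return k, v


def build_reference(
    g_pp: GRM | np.ndarray,
    z_pp: RecordCounts,
    params: ModelParams,
    ids: tuple[str, ...] | None = None,
) -> ReferenceState:
    """Invert M = G_pp + alpha*diag(1/z) once, by Cholesky, for the core.

    All core animals must be phenotyped (z >= 1).  ``g_pp`` is either a
    :class:`~gblupacc.grm.GRM` (its ids are used) or a plain symmetric
    array plus explicit ``ids``.
    """
    if isinstance(g_pp, GRM):
        values = g_pp.values
        ids = g_pp.ids
        gdiag = g_pp.diagonal()
    else:
        values = np.asarray(g_pp, dtype=float)
        values = (values + values.T) / 2.0
        if ids is None:
            ids = tuple(f"core{i + 1}" for i in range(values.shape[0]))
        gdiag = np.diag(values).copy()
    p = values.shape[0]
    if len(z_pp) != p:
        raise DimensionError(f"{len(z_pp)} record counts for {p} core individuals")
    if (z_pp.counts < 1).any():
        raise ValidationError(
            "core animals must be phenotyped: every core record count must be >= 1"
        )
    m = values + np.diag(params.alpha / z_pp.counts)
    try:
        c, low = linalg.cho_factor(m, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise NotPositiveDefiniteError(
            f"M = G_pp + alpha*(Z'Z)_pp^-1 is not positive definite: {exc}"
        ) from None
    minv = linalg.cho_solve((c, low), np.eye(p), check_finite=False)
    return ReferenceState(
        core_ids=tuple(ids), alpha=params.alpha, minv=minv, core_grm_diag=gdiag
    )


def cqq_with_phenotype(state: ReferenceState, ind: NewIndividual) -> float:
    """c^qq for a phenotyped new individual: k / (k*z_qq + alpha)."""
    if ind.z_qq < 1:
        raise WrongOperationError(
            f"individual {ind.id!r} has no phenotype records; use "
            "cqq_without_phenotype"
        )
    k, _ = _schur_residual(state, ind)
    return k / (k * ind.z_qq + state.alpha)


def cqq_without_phenotype(state: ReferenceState, ind: NewIndividual) -> float:
    """c^qq for an unphenotyped new individual: k / alpha (the z -> 0 limit).

    The resulting reliability 1 - alpha*c^qq/g_qq equals
    g_pq' M^-1 g_pq / g_qq: all information flows through relatives.
    """
    if ind.z_qq != 0:
        raise WrongOperationError(
            f"individual {ind.id!r} has {ind.z_qq} phenotype records; use "
            "cqq_with_phenotype"
        )
    k, _ = _schur_residual(state, ind)
    return k / state.alpha


def score_new_individual(state: ReferenceState, ind: NewIndividual) -> AccuracyResult:
    """Dispatch on z_qq and convert c^qq to reliability/accuracy."""
    if ind.z_qq >= 1:
        cqq = cqq_with_phenotype(state, ind)
    else:
        cqq = cqq_without_phenotype(state, ind)
    return henderson_scores(
        cqq=cqq,
        g_ii=ind.g_qq,
        params=ModelParams(alpha=state.alpha),
        phenotyped=ind.z_qq >= 1,
        id=ind.id,
    )


def schur_update_parts(state: ReferenceState, ind: NewIndividual) -> SchurUpdateParts:
    """All intermediates of the block update, for inspection/testing."""
    k, v = _schur_residual(state, ind)
    if ind.z_qq < 1:
        return SchurUpdateParts(k=k, s=None, sn2=None, sn4=None)
    s = k + state.alpha / ind.z_qq
    return SchurUpdateParts(k=k, s=s, sn2=-v / s, sn4=1.0 / s)


def update_reference(state: ReferenceState, ind: NewIndividual) -> ReferenceState:
    """Grow M^-1 by one phenotyped animal with the Schur block-inverse rule.

    With v = M^-1 g_pq and s = g_qq + alpha/z_qq - g_pq' v:

        new M^-1 = [ M^-1 + v v'/s ,  -v/s ]
                   [   -v'/s       ,   1/s ]

    The result equals a from-scratch :func:`build_reference` on the
    augmented core.  The new animal must be phenotyped (z_qq >= 1): the
    model's M needs alpha/z on its diagonal, which is undefined at z = 0.
    """
    if ind.z_qq < 1:
        raise ValidationError(
            f"cannot add unphenotyped individual {ind.id!r} to the core: "
            "the reference update needs a phenotype record count >= 1"
        )
    if ind.id in state.core_ids:
        raise ValidationError(f"individual {ind.id!r} is already in the core")
    k, v = _schur_residual(state, ind)
    s = k + state.alpha / ind.z_qq
    if s <= 0:
        raise NotPositiveDefiniteError(
            f"Schur complement s = {s} <= 0: augmented M not positive definite"
        )
    p = state.n_core
    new = np.empty((p + 1, p + 1))
    new[:p, :p] = state.minv + np.outer(v, v) / s
    new[:p, p] = -v / s
    new[p, :p] = -v / s
    new[p, p] = 1.0 / s
    diag = None
    if state.core_grm_diag is not None:
        diag = np.append(state.core_grm_diag, ind.g_qq)
    return ReferenceState(
        core_ids=state.core_ids + (ind.id,),
        alpha=state.alpha,
        minv=new,
        core_grm_diag=diag,
    )


# ---------------------------------------------------------------------------
# persistence: little-endian binary state file
#
#   magic "MINV" | u32 version | u8 flags | u64 p | f64 alpha
#   p * (u32 len | utf-8 id bytes)
#   u64 payload_len | payload | u32 crc32(payload)
#
# payload = row-major f64 minv [+ f64 core_grm_diag if flagged], zlib-
# compressed when the compression flag is set.
# ---------------------------------------------------------------------------


def save_state(state: ReferenceState, path: str | Path, compress: bool = False) -> None:
    """Write a reference state to ``path`` (lossless, bit-exact round trip)."""
    p = state.n_core
    flags = 0
    payload = state.minv.astype("<f8").tobytes(order="C")
    if state.core_grm_diag is not None:
        flags |= _FLAG_HAS_DIAG
        payload += state.core_grm_diag.astype("<f8").tobytes()
    if compress:
        flags |= _FLAG_COMPRESSED
        payload = zlib.compress(payload)
    with open(path, "wb") as fh:
        fh.write(STATE_MAGIC)
        fh.write(struct.pack("<IBQd", state.version, flags, p, state.alpha))
        for cid in state.core_ids:
            raw = cid.encode("utf-8")
            fh.write(struct.pack("<I", len(raw)))
            fh.write(raw)
        fh.write(struct.pack("<Q", len(payload)))
        fh.write(payload)
        fh.write(struct.pack("<I", zlib.crc32(payload) & 0xFFFFFFFF))


def _read_exact(fh, n: int, what: str) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise StateIntegrityError(f"truncated state file while reading {what}")
    return data


def load_state(path: str | Path) -> ReferenceState:
    """Read a reference state written by :func:`save_state`."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != STATE_MAGIC:
            raise StateFormatError(
                f"bad magic bytes {magic!r}: not a gblupacc reference-state file"
            )
        version, flags, p, alpha = struct.unpack(
            "<IBQd", _read_exact(fh, struct.calcsize("<IBQd"), "header")
        )
        if version != STATE_VERSION:
            raise StateFormatError(f"unsupported state-file version {version}")
        ids = []
        for i in range(p):
            (ln,) = struct.unpack("<I", _read_exact(fh, 4, f"id {i} length"))
            ids.append(_read_exact(fh, ln, f"id {i}").decode("utf-8"))
        (payload_len,) = struct.unpack("<Q", _read_exact(fh, 8, "payload length"))
        payload = _read_exact(fh, payload_len, "matrix payload")
        (crc,) = struct.unpack("<I", _read_exact(fh, 4, "checksum"))
    if zlib.crc32(payload) & 0xFFFFFFFF != crc:
        raise StateIntegrityError("state-file checksum mismatch: payload corrupted")
    if flags & _FLAG_COMPRESSED:
        payload = zlib.decompress(payload)
    n_mat = p * p * 8
    expected = n_mat + (p * 8 if flags & _FLAG_HAS_DIAG else 0)
    if len(payload) != expected:
        raise StateIntegrityError(
            f"payload has {len(payload)} bytes, expected {expected}"
        )
    minv = np.frombuffer(payload[:n_mat], dtype="<f8").reshape(p, p).copy()
    diag = None
    if flags & _FLAG_HAS_DIAG:
        diag = np.frombuffer(payload[n_mat:], dtype="<f8").copy()
    return ReferenceState(
        core_ids=tuple(ids), alpha=alpha, minv=minv, core_grm_diag=diag,
        version=version,
    )
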
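"""Reading, writing and log-odds conversion of profile hidden Markov models.

Supports the HMMER3 ASCII ``.hmm`` format (``HMMER3/b`` and ``HMMER3/f``
headers, multi-model files). Probabilities in the file are stored as negative
natural logs with ``*`` denoting probability zero; we recover plain
probabilities at parse time and renormalise each distribution, since the
5-decimal fixed-point encoding leaves row sums ~1e-6 away from one.

Only the core M/I/D states are modelled. Plan7 special states (B/E/N/C/J)
are not represented: alignment locality is handled explicitly by the seeding
and extension machinery, so local entry/exit is free rather than governed by
special-state transitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._alphabet import AMINO_ACIDS, N_AA

#: Transition ordering, matching the HMMER3 node-transition line
#: ``m->m m->i m->d i->m i->i d->m d->d``; row index = source node.
TRANSITIONS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

NEG_INF = -np.inf


class HMMParseError(ValueError):
    """Raised for malformed HMMER3 text input; carries the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


@dataclass
class ProfileHMM:
    """A profile HMM over the 20 amino acids.

    Arrays are 1-based in the model dimension: row ``i`` of ``match_emit`` /
    ``insert_emit`` / ``trans`` belongs to node ``i``; row 0 holds the
    begin-node insert emissions and transitions.
    """

    name: str
    L: int
    match_emit: np.ndarray  # (L+1, 20); row 0 unused
    insert_emit: np.ndarray  # (L+1, 20)
    trans: np.ndarray  # (L+1, 7)
    background: np.ndarray  # (20,)
    meta: dict = field(default_factory=dict)

    def validate(self, tol: float = 1e-6) -> None:
        if self.L < 1:
            raise ValueError("model must have at least one match state")
        if abs(self.background.sum() - 1.0) > tol:
            raise ValueError("background does not sum to 1")
        for i in range(1, self.L + 1):
            for arr, label in ((self.match_emit, "match"), (self.insert_emit, "insert")):
                s = arr[i].sum()
                # node-L insert emissions may be vestigial in some files
                if label == "insert" and i == self.L and s == 0.0:
                    continue
                if abs(s - 1.0) > tol:
                    raise ValueError(f"{label} emission row {i} sums to {s}")
        for i in range(1, self.L):
            t = self.trans[i]
            for idx, label in (((T_MM, T_MI, T_MD), "M"), ((T_IM, T_II), "I"), ((T_DM, T_DD), "D")):
                s = sum(t[j] for j in idx)
                if abs(s - 1.0) > tol:
                    raise ValueError(f"{label} transitions at node {i} sum to {s}")


@dataclass
class ScoringModel:
    """Log-odds (bits) form of a :class:`ProfileHMM` used by the DP.

    ``emit_M[i, a] = log2(match_emit[i, a] / background[a])``; zero
    probabilities map to ``-inf``. Transition scores ``tr`` are plain
    ``log2`` probabilities (always <= 0).
    """

    name: str
    L: int
    emit_M: np.ndarray  # (L+1, 20) bits
    emit_I: np.ndarray  # (L+1, 20) bits
    tr: np.ndarray  # (L+1, 7) bits
    background: np.ndarray

    def consensus(self) -> str:
        """Per-state argmax match residue (ties broken by alphabet order)."""
        idx = np.argmax(self.emit_M[1:], axis=1)
        return "".join(AMINO_ACIDS[j] for j in idx)


def _log2_safe(p: np.ndarray) -> np.ndarray:
    out = np.full(p.shape, NEG_INF)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


def to_scoring(model: ProfileHMM, background: Sequence[float] | None = None) -> ScoringModel:
    """Convert probabilities to bit-scaled log-odds scores.

    ``background`` defaults to the model's stated (COMPO) background, falling
    back to uniform 1/20 if the file carried none.
    """
    if background is None:
        bg = np.asarray(model.background, dtype=float)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (N_AA,):
            raise ValueError("background must have 20 entries")
        bg = bg / bg.sum()
    log_bg = _log2_safe(bg)
    emit_M = _log2_safe(model.match_emit) - log_bg[None, :]
    emit_I = _log2_safe(model.insert_emit) - log_bg[None, :]
    # row 0 match state does not exist
    emit_M[0, :] = NEG_INF
    emit_M[np.isnan(emit_M)] = NEG_INF
    emit_I[np.isnan(emit_I)] = NEG_INF
    tr = _log2_safe(model.trans)
    return ScoringModel(model.name, model.L, emit_M, emit_I, tr, bg)


def from_scoring_emissions(scoring: ScoringModel) -> np.ndarray:
    """Inverse transform: recover match emission probabilities (test oracle)."""
    return np.power(2.0, scoring.emit_M) * scoring.background[None, :]


# ---------------------------------------------------------------------------
# HMMER3 ASCII parsing


def _prob(tok: str, line_no: int) -> float:
    if tok == "*":
        return 0.0
    try:
        return math.exp(-float(tok))
    except ValueError as exc:
        raise HMMParseError(f"bad probability field {tok!r}", line_no) from exc


def _normalised(row: np.ndarray) -> np.ndarray:
    s = row.sum()
    return row / s if s > 0 else row


def parse_hmm(path: str | Path) -> list[ProfileHMM]:
    """Parse all records of an HMMER3 ASCII file.

    Raises :class:`HMMParseError` (with line number) on malformed headers,
    non-amino alphabets or truncated records.
    """
    models: list[ProfileHMM] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith("HMMER3"):
            raise HMMParseError(f"expected HMMER3 header, got {line[:40]!r}", i + 1)
        header_line = i + 1
        i += 1
        name = None
        L = None
        alph = None
        meta: dict = {}
        while i < n:
            stripped = lines[i].rstrip("\n")
            parts = stripped.split()
            if parts and parts[0] == "HMM":
                break
            if len(parts) >= 2:
                key = parts[0]
                val = stripped[len(key):].strip()
                if key == "NAME":
                    name = val
                elif key == "LENG":
                    try:
                        L = int(val)
                    except ValueError:
                        raise HMMParseError(f"bad LENG {val!r}", i + 1)
                elif key == "ALPH":
                    alph = val.lower()
                else:
                    meta[key] = val
            i += 1
        else:
            raise HMMParseError("truncated record: no HMM line", header_line)
        if name is None:
            name = f"model{len(models) + 1}"
        if L is None:
            raise HMMParseError("record missing LENG", header_line)
        if alph != "amino":
            raise HMMParseError(f"unsupported alphabet {alph!r} (need amino)", header_line)
        # symbol header + transition-name header
        sym_parts = lines[i].split()
        if sym_parts[1:] != list(AMINO_ACIDS):
            raise HMMParseError("HMM symbol line does not list the 20 amino acids", i + 1)
        i += 2

        background = np.full(N_AA, 1.0 / N_AA)
        match_emit = np.zeros((L + 1, N_AA))
        insert_emit = np.zeros((L + 1, N_AA))
        trans = np.zeros((L + 1, 7))

        parts = lines[i].split()
        if parts and parts[0] == "COMPO":
            if len(parts) != N_AA + 1:
                raise HMMParseError("COMPO line must carry 20 fields", i + 1)
            background = _normalised(
                np.array([_prob(t, i + 1) for t in parts[1:]])
            )
            i += 1
        # node 0: insert emissions, then transitions
        parts = lines[i].split()
        if len(parts) < N_AA:
            raise HMMParseError("truncated node-0 insert line", i + 1)
        insert_emit[0] = _normalised(np.array([_prob(t, i + 1) for t in parts[:N_AA]]))
        i += 1
        parts = lines[i].split()
        if len(parts) < 7:
            raise HMMParseError("truncated node-0 transition line", i + 1)
        trans[0] = [_prob(t, i + 1) for t in parts[:7]]
        i += 1
        for node in range(1, L + 1):
            if i + 2 >= n:
                raise HMMParseError(f"truncated record inside node {node}", i + 1)
            parts = lines[i].split()
            if len(parts) < N_AA + 1:
                raise HMMParseError(f"truncated match line for node {node}", i + 1)
            try:
                got = int(parts[0])
            except ValueError:
                raise HMMParseError(f"expected node number, got {parts[0]!r}", i + 1)
            if got != node:
                raise HMMParseError(f"expected node {node}, got {got}", i + 1)
            match_emit[node] = _normalised(
                np.array([_prob(t, i + 1) for t in parts[1:N_AA + 1]])
            )
            i += 1
            parts = lines[i].split()
            if len(parts) < N_AA:
                raise HMMParseError(f"truncated insert line for node {node}", i + 1)
            row = np.array([_prob(t, i + 1) for t in parts[:N_AA]])
            insert_emit[node] = _normalised(row) if row.sum() > 0 else row
            i += 1
            parts = lines[i].split()
            if len(parts) < 7:
                raise HMMParseError(f"truncated transition line for node {node}", i + 1)
            trans[node] = [_prob(t, i + 1) for t in parts[:7]]
            i += 1
        # renormalise transition groups
        for node in range(L + 1):
            for idx in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
                s = sum(trans[node, j] for j in idx)
                if s > 0:
                    for j in idx:
                        trans[node, j] /= s
        if i >= n or lines[i].strip() != "//":
            raise HMMParseError("record not terminated by //", min(i + 1, n))
        i += 1
        model = ProfileHMM(name, L, match_emit, insert_emit, trans, background, meta)
        model.validate(tol=1e-5)
        models.append(model)
    if not models:
        raise HMMParseError("file contains no HMM records", 1)
    return models


def _fmt(p: float) -> str:
    return "*" if p <= 0.0 else f"{-math.log(p):.6f}"


def write_hmm(models: Iterable[ProfileHMM] | ProfileHMM, path: str | Path) -> None:
    """Write models in HMMER3/f ASCII format (6-decimal fields for fidelity)."""
    if isinstance(models, ProfileHMM):
        models = [models]
    with open(path, "w") as fh:
        for m in models:
            fh.write("HMMER3/f [prosaa]\n")
            fh.write(f"NAME  {m.name}\n")
            fh.write(f"LENG  {m.L}\n")
            fh.write("ALPH  amino\n")
            fh.write("HMM          " + "        ".join(AMINO_ACIDS) + "\n")
            fh.write("            m->m     m->i     m->d     i->m     i->i     d->m     d->d\n")
            fh.write("  COMPO   " + "  ".join(_fmt(p) for p in m.background) + "\n")
            fh.write("          " + "  ".join(_fmt(p) for p in m.insert_emit[0]) + "\n")
            fh.write("          " + "  ".join(_fmt(p) for p in m.trans[0]) + "\n")
            for node in range(1, m.L + 1):
                cons = AMINO_ACIDS[int(np.argmax(m.match_emit[node]))].lower()
                fh.write(f"{node:7d}   " + "  ".join(_fmt(p) for p in m.match_emit[node])
                         + f"  {node:7d} {cons} - - -\n")
                fh.write("          " + "  ".join(_fmt(p) for p in m.insert_emit[node]) + "\n")
                fh.write("          " + "  ".join(_fmt(p) for p in m.trans[node]) + "\n")
            fh.write("//\n")
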
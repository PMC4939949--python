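"""Synthetic benchmark generator.

Emulates the desk-scale analogue of a metagenomic benchmark: homolog
proteins are sampled from profile HMMs, embedded among decoy proteins drawn
i.i.d. from the background composition, and every protein is fragmented
into overlapping peptide reads of a fixed length (default 33 aa, the
peptide-space equivalent of translated 100-bp reads) at a configurable
coverage with i.i.d. substitution errors (default 1%). Ground truth labels a
read with a family iff it overlaps that family's homologous region by more
than 60% of the read — the same rule the mapper uses for recruitment.

Simulation operates directly in peptide space: nucleotide sequencing and
fragmentary gene calling happen upstream of the tool's input contract and
are not modelled (no indels, no chimeras, no quality values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._alphabet import AMINO_ACIDS
from .hmmio import ProfileHMM, T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM


@dataclass
class SimProtein:
    id: str
    seq: str
    family: str | None  # None for decoys
    region: tuple[int, int] | None  # homologous region (here: the whole protein)


@dataclass
class SimRead:
    id: str
    seq: str
    protein_id: str
    start: int  # position in the source protein
    families: tuple[str, ...]  # ground-truth labels


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset."""

    n_homologs: int = 2  # homolog proteins per family
    n_decoys: int = 200
    decoy_len_range: tuple[int, int] = (120, 350)
    coverage: float = 10.0  # per-protein sequencing depth
    read_len: int = 33  # aa; translation-scale of 100-bp reads
    error_rate: float = 0.01  # per-residue substitution probability
    truth_min_portion: float = 0.6  # overlap fraction for truth labels (strict >)
    seed: int = 0

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error rate must be in [0, 1)")


# ---------------------------------------------------------------------------
# model construction and sampling


def random_profile_hmm(L: int, seed: int, name: str | None = None,
                       conservation: float = 0.75,
                       background: np.ndarray | None = None) -> ProfileHMM:
    """A random peaked profile HMM for fixtures and benchmarks.

    Each match state concentrates ``conservation`` probability on a random
    consensus residue, with the remainder spread by a Dirichlet draw; insert
    states emit the background; transitions favour M->M (0.93).
    """
    rng = np.random.default_rng(seed)
    bg = (np.full(20, 0.05) if background is None
          else np.asarray(background, dtype=float))
    match = np.zeros((L + 1, 20))
    insert = np.zeros((L + 1, 20))
    trans = np.zeros((L + 1, 7))
    insert[0] = bg
    trans[0] = [0.95, 0.02, 0.03, 0.8, 0.2, 0.9, 0.1]
    cons = rng.integers(0, 20, size=L + 1)
    for i in range(1, L + 1):
        row = rng.dirichlet(np.full(20, 0.3))
        p = (1 - conservation) * row
        p[cons[i]] += conservation
        match[i] = p / p.sum()
        insert[i] = bg
        trans[i] = [0.93, 0.04, 0.03, 0.85, 0.15, 0.9, 0.1]
    # last node: M->E certain, no insert/delete continuation
    trans[L] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]
    m = ProfileHMM(name or f"FAM{seed}", L, match, insert, trans, bg)
    m.validate()
    return m


def sample_from_hmm(model: ProfileHMM, seed: int | np.random.Generator) -> tuple[str, list[str]]:
    """Emit one sequence by stochastic traversal of the model's M/I/D states.

    Returns the peptide and the generating state path (e.g. ``["M1", "I1",
    "M2", ...]``). The same seed always yields the same sequence.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq: list[str] = []
    path: list[str] = []
    L = model.L
    t0 = model.trans[0]
    state, node = _choose(rng, (("M", 1, t0[T_MM]), ("I", 0, t0[T_MI]), ("D", 1, t0[T_MD])))
    while True:
        if state == "M":
            a = rng.choice(20, p=model.match_emit[node])
            seq.append(AMINO_ACIDS[a])
            path.append(f"M{node}")
            if node == L:
                break
            t = model.trans[node]
            state, node = _choose(rng, (("M", node + 1, t[T_MM]), ("I", node, t[T_MI]),
                                        ("D", node + 1, t[T_MD])))
        elif state == "I":
            a = rng.choice(20, p=model.insert_emit[node])
            seq.append(AMINO_ACIDS[a])
            path.append(f"I{node}")
            t = model.trans[node]
            state, node = _choose(rng, (("M", node + 1, t[T_IM]), ("I", node, t[T_II])))
        else:  # D
            path.append(f"D{node}")
            if node == L:
                break
            t = model.trans[node]
            state, node = _choose(rng, (("M", node + 1, t[T_DM]), ("D", node + 1, t[T_DD])))
    return "".join(seq), path


def _choose(rng, options):
    probs = np.array([o[2] for o in options], dtype=float)
    s = probs.sum()
    if s <= 0:
        raise ValueError("no outgoing transition probability")
    idx = rng.choice(len(options), p=probs / s)
    return options[idx][0], options[idx][1]


# ---------------------------------------------------------------------------
# dataset generation


def make_proteins(families: dict[str, ProfileHMM], config: SimConfig,
                  rng: np.random.Generator) -> list[SimProtein]:
    """Homologs sampled from each family model plus background decoys."""
    proteins: list[SimProtein] = []
    for fam in sorted(families):
        for h in range(config.n_homologs):
            seq, _ = sample_from_hmm(families[fam], rng)
            proteins.append(SimProtein(f"{fam}_homolog{h}", seq, fam, (0, len(seq))))
    bg = np.full(20, 0.05)
    lo, hi = config.decoy_len_range
    for d in range(config.n_decoys):
        n = int(rng.integers(lo, hi + 1))
        seq = "".join(AMINO_ACIDS[a] for a in rng.choice(20, size=n, p=bg))
        proteins.append(SimProtein(f"decoy{d}", seq, None, None))
    return proteins


def simulate_reads(proteins: list[SimProtein], config: SimConfig,
                   rng: np.random.Generator | None = None) -> list[SimRead]:
    """Fragment proteins into error-bearing reads with ground-truth labels.

    Per protein, ``round(coverage * length / read_len)`` reads start at
    uniform positions; substitutions hit each residue i.i.d. at the error
    rate (replacement uniform over the other 19 residues). A protein shorter
    than the read length is emitted whole.
    """
    if not proteins:
        raise ValueError("no proteins to sequence")
    rng = rng or np.random.default_rng(config.seed)
    reads: list[SimRead] = []
    counter = 0
    for prot in proteins:
        plen = len(prot.seq)
        rl = min(config.read_len, plen)
        n_reads = int(round(config.coverage * plen / config.read_len))
        for _ in range(n_reads):
            start = int(rng.integers(0, plen - rl + 1))
            frag = list(prot.seq[start:start + rl])
            for p in range(len(frag)):
                if rng.random() < config.error_rate:
                    cur = frag[p]
                    choices = [c for c in AMINO_ACIDS if c != cur]
                    frag[p] = choices[int(rng.integers(0, 19))]
            labels = _truth_labels(prot, start, rl, config.truth_min_portion)
            reads.append(SimRead(
                id=f"r{counter}|{prot.id}|{start}", seq="".join(frag),
                protein_id=prot.id, start=start, families=labels))
            counter += 1
    return reads


def _truth_labels(prot: SimProtein, start: int, read_len: int,
                  min_portion: float) -> tuple[str, ...]:
    if prot.family is None or prot.region is None:
        return ()
    lo = max(start, prot.region[0])
    hi = min(start + read_len, prot.region[1])
    if (hi - lo) / read_len > min_portion:
        return (prot.family,)
    return ()


def truth_sets(reads: list[SimRead]) -> dict[str, set[str]]:
    """family -> set of truth-labeled read ids."""
    out: dict[str, set[str]] = {}
    for r in reads:
        for fam in r.families:
            out.setdefault(fam, set()).add(r.id)
    return out


# ---------------------------------------------------------------------------
# file output (CLI `simulate`)


def write_dataset(outdir: str | Path, families: dict[str, ProfileHMM],
                  proteins: list[SimProtein], reads: list[SimRead],
                  config: SimConfig) -> dict[str, Path]:
    """Write reads FASTA, proteins FASTA, truth TSV and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.faa",
        "proteins": outdir / "proteins.faa",
        "truth": outdir / "truth.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["reads"], "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.seq}\n")
    with open(paths["proteins"], "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("# read_id\tfamily\n")
        for r in reads:
            for fam in r.families:
                fh.write(f"{r.id}\t{fam}\n")
    manifest = {
        "families": {f: m.L for f, m in families.items()},
        "n_proteins": len(proteins),
        "n_reads": len(reads),
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
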
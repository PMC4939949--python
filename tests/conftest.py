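import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prosaa.readdb import PeptideRead, ReadDatabase
from prosaa.synthetic import random_profile_hmm

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


def db_from_seqs(seqs, prefix="r"):
    return ReadDatabase(
        [PeptideRead(f"{prefix}{i}", s, i) for i, s in enumerate(seqs)])


@pytest.fixture(scope="session")
def small_model():
    """A 30-state peaked profile HMM shared across tests."""
    return random_profile_hmm(30, seed=11, name="SMALL")


@pytest.fixture(scope="session")
def toy_hmm_text(tmp_path_factory):
    """A hand-written 2-node HMMER3/b record with known probabilities."""
    # -ln(p): 0.693147 ~ 0.5, 1.386294 ~ 0.25, 2.995732 ~ 0.05
    ins = "  ".join(["2.995732"] * 20)  # uniform 0.05
    m1 = "  ".join(["0.693147"] + ["3.664520"] * 19)  # A=0.5, rest ~0.0256
    m2 = "  ".join(["3.664520"] * 5 + ["0.693147"] + ["3.664520"] * 14)  # G=0.5
    text = f"""HMMER3/b [3.1b2 | toy]
NAME  TOY2
LENG  2
ALPH  amino
HMM          A        C        D        E        F        G        H        I        K        L        M        N        P        Q        R        S        T        V        W        Y
            m->m     m->i     m->d     i->m     i->i     d->m     d->d
  COMPO   {ins}
          {ins}
          0.010050  5.298317  4.605170  0.693147  0.693147  *  *
      1   {m1}
          {ins}
          0.105361  2.302585  3.506558  0.693147  0.693147  0.693147  0.693147
      2   {m2}
          {ins}
          0.000000  *  *  1.000000  *  0.000000  *
//
"""
    path = tmp_path_factory.mktemp("hmm") / "toy.hmm"
    path.write_text(text)
    return path
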
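import numpy as np
import pytest

import evirank as ev


@pytest.fixture(scope="session")
def lexicons():
    return ev.load_lexicons()


@pytest.fixture(scope="session")
def fixture_docs():
    return ev.build_fixtures()


@pytest.fixture(scope="session")
def paper_corpus(lexicons):
    """Generated paper-like corpus with its extracted feature vectors."""
    docs = ev.generate_corpus(ev.paper_like_params(seed=7))
    candidates = []
    for d in docs:
        candidates.extend(ev.assemble_candidates(d, lexicons))
    vectors = ev.extract_features(candidates, lexicons)
    return docs, candidates, vectors


def random_tree_tokens(rng: np.random.Generator, n: int):
    """A uniform random recursive tree over n tokens (node 0 is root)."""
    rows = [ev.Token(index=0, surface="w0", lemma="w0", head=-1,
                     deplabel="root")]
    for i in range(1, n):
        head = int(rng.integers(0, i))
        rows.append(ev.Token(index=i, surface=f"w{i}", lemma=f"w{i}",
                             head=head, deplabel="dep"))
    return rows
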
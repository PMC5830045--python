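import random
import string

import pytest

from ammlib import AmLibrary, build_demo_library, make_record


@pytest.fixture
def demo_library() -> AmLibrary:
    return build_demo_library()


def make_random_library(rng: random.Random,
                        n_models: int | None = None,
                        n_data: int | None = None) -> AmLibrary:
    """A small library with random names, metadata, and data links.

    Names are drawn from a themed pool so that patterns like a shared
    word sometimes match several records; roughly half the models carry a
    "data" link, which may or may not resolve within the library
    (dangling links are legal and must be tolerated everywhere).
    """
    words = ["frog", "plant", "apple", "deer", "marsh", "site", "survey"]

    def name(prefix: str) -> str:
        return (f"{rng.choice(words)}.{prefix}"
                f"{rng.randint(1, 50)}{rng.choice(string.ascii_lowercase)}")

    def metadata() -> dict:
        meta = {"comment": " ".join(rng.choices(words, k=rng.randint(1, 4)))}
        if rng.random() < 0.5:
            meta[rng.choice(["taxa", "owner", "season"])] = rng.choice(words)
        return meta

    lib = AmLibrary("random fixture library", {"owner": "tester"})
    if n_data is None:
        n_data = rng.randint(0, 5)
    if n_models is None:
        n_models = rng.randint(0, 5)
    data_names: list[str] = []
    while len(data_names) < n_data:
        n = name("data")
        if n not in data_names:
            data_names.append(n)
    for n in data_names:
        lib.insert(data={n: make_record("data", {"value": rng.random()},
                                        metadata())})
    model_names: list[str] = []
    while len(model_names) < n_models:
        n = name("model")
        if n not in model_names:
            model_names.append(n)
    for n in model_names:
        meta = metadata()
        if rng.random() < 0.5:
            if data_names and rng.random() < 0.8:
                meta["data"] = rng.choice(data_names)
            else:
                meta["data"] = "nonexistent.data"  # dangling link
        lib.insert(models={n: make_record("model", {"coef": rng.random()},
                                          meta)})
    return lib
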
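import numpy as np
import pandas as pd
import pytest

from viralmil.bags import Instance, VirusBag
from viralmil.datasets import RANKS, TABLE_COLUMNS
from viralmil.mil_core import MILConfig, init_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_bag(rng, virus_id="v1", m=None, dim=6, label=1):
    m = m or int(rng.integers(2, 8))
    return VirusBag(
        virus_id=virus_id,
        instances=[Instance(protein_id=f"{virus_id}_p{j}") for j in range(m)],
        features=rng.normal(size=(m, dim)),
        label=label,
    )


@pytest.fixture
def small_params(rng):
    config = MILConfig(input_dim=6, hidden_dim=9, attention_dim=4)
    return init_parameters(config, rng), config


def toy_table():
    """A hand-built association table with a nested two-phylum taxonomy.

    hostA and hostB share a genus; hostC shares only the family; hostD the
    order; hostE the class; hostF the phylum; hostG sits in a different
    phylum. Virus counts per host are fixed so eligibility thresholds are
    easy to reason about.
    """
    lineages = {
        "hostA": dict(genus="g1", family="f1", order="o1", class_="c1", phylum="p1"),
        "hostB": dict(genus="g1", family="f1", order="o1", class_="c1", phylum="p1"),
        "hostC": dict(genus="g2", family="f1", order="o1", class_="c1", phylum="p1"),
        "hostD": dict(genus="g3", family="f2", order="o1", class_="c1", phylum="p1"),
        "hostE": dict(genus="g4", family="f3", order="o2", class_="c1", phylum="p1"),
        "hostF": dict(genus="g5", family="f4", order="o3", class_="c2", phylum="p1"),
        "hostG": dict(genus="g6", family="f5", order="o4", class_="c3", phylum="p2"),
    }
    counts = {"hostA": 6, "hostB": 4, "hostC": 4, "hostD": 4, "hostE": 4,
              "hostF": 4, "hostG": 6}
    rows = []
    v = 0
    for host, n in counts.items():
        lin = lineages[host]
        for _ in range(n):
            rows.append({
                "virus_id": f"v{v:03d}", "virus_name": f"virus {v}",
                "virus_genus": f"vg{v % 8}", "refseq_ids": f"NC_{v:06d}",
                "host_id": host, "host_name": host, "host_domain": "prokaryote",
                "host_genus": lin["genus"], "host_family": lin["family"],
                "host_order": lin["order"], "host_class": lin["class_"],
                "host_phylum": lin["phylum"], "host_kingdom": "k1",
            })
            v += 1
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


@pytest.fixture
def association_table():
    return toy_table()
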
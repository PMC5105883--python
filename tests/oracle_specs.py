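"""The 50 fixture specs used for the frozen independent-parse comparison.

The expected values in ``data/oracle_expected.json`` were produced by an
independent grammar-driven DOT parser run over the serializer's output
for exactly these specs; regenerating the fixtures from the same seeds
must reproduce the same topology and resolved attribute maps.
"""

from dotcyto.fixtures import FixtureSpec


def oracle_specs() -> list[FixtureSpec]:
    return [
        FixtureSpec(
            seed=1000 + i,
            n_nodes=2 + (i % 5),
            edge_prob=0.35,
            directed=bool(i % 2),
            attr_density=0.3,
        )
        for i in range(50)
    ]
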
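"""Shared test fixtures: the published flat-file excerpt and a small
synthetic bundle covering every scenario."""

from __future__ import annotations

import io

import pytest

from ppimut import fixtures, tsvio

# The published flat-file excerpt: 5 features over 6 rows (EBI-4370347 is a
# two-position feature spanning two rows). Original sequence "D" against
# label Asn31 on EBI-4370347 is a known label/column conflict in the source
# and is preserved verbatim.
TABLE1_TSV = "\t".join(tsvio.COLUMNS) + "\n" + "\n".join(
    "\t".join(row)
    for row in [
        ["EBI-10828532", "p.Arg725Glu", "725-725", "R", "E",
         "mutation(MI:0118)",
         "MI:0612 (comment): Disrupts association with VPS33A and decreases association of VPS18",
         "Q9P253", "VPS18", "9606", "EBI-I0000001", "Q5KU39", "pull down(MI:0096)",
         "PMID:100001", "IntAct"],
        ["EBI-985220", "p.Ile114Gly", "114-114", "I", "G",
         "mutation increasing interaction(MI:0382)", "", "P60953", "CDC42", "9606",
         "EBI-I0000002", "Q92974", "two hybrid(MI:0018)", "PMID:100002", "IntAct"],
        ["EBI-4370347", "p.[Asn31His;Ala60Val]", "31-31", "D", "H",
         "mutation increasing interaction(MI:0382)", "- (kd): 11e-9M", "P12931",
         "SRC", "9606", "EBI-I0000003", "P00533", "pull down(MI:0096)",
         "PMID:100003", "MINT"],
        ["EBI-4370347", "p.[Asn31His;Ala60Val]", "60-60", "A", "V",
         "mutation increasing interaction(MI:0382)", "- (kd): 11e-9M", "P12931",
         "SRC", "9606", "EBI-I0000003", "P00533", "pull down(MI:0096)",
         "PMID:100003", "MINT"],
        ["EBI-10688294", "p.Thr2Ala", "2-2", "T", "A",
         "mutation decreasing interaction rate(MI:1130)", "", "P49841", "GSK3B",
         "9606", "EBI-I0000004", "O15169", "pull down(MI:0096)", "PMID:100004",
         "IntAct"],
        ["EBI-9635600", "p.Cys_Ser215-216Ala_Ala", "215-216", "CS", "AA",
         "mutation disrupting interaction(MI:0573)", "", "P35222", "CTNNB1",
         "9606", "EBI-I0000005", "Q9UJU2", "two hybrid(MI:0018)", "PMID:100005",
         "DIP"],
    ]
) + "\n"

TABLE1_LABELS = [
    "p.Arg725Glu",
    "p.Ile114Gly",
    "p.[Asn31His;Ala60Val]",
    "p.Thr2Ala",
    "p.Cys_Ser215-216Ala_Ala",
]


@pytest.fixture(scope="session")
def table1_features():
    return tsvio.read_mutations_table(io.StringIO(TABLE1_TSV))


@pytest.fixture(scope="session")
def small_spec():
    return fixtures.FixtureSpec(
        seed=7,
        effect_counts={"disrupting": 30, "decreasing": 20, "increasing": 6,
                       "causing": 2, "no_effect": 8, "undefined": 4},
        consistency=fixtures.ConsistencyScenario(
            n_multi_groups=60, n_mild=5, n_conflict=3, n_single_groups=4
        ),
        variants=fixtures.VariantScenario(),
        phospho=fixtures.PhosphoScenario(),
        interface=fixtures.InterfaceScenario(),
        organisms=[
            fixtures.OrganismComposition("9606", 40, 20, 5, 10, 6),
            fixtures.OrganismComposition("10090", 15, 10, 3, 5, 4),
        ],
        qc=fixtures.QCScenario(n_unchanged=8, n_shifted=5, n_flagged=3),
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return fixtures.generate(small_spec)
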
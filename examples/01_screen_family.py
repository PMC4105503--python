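"""Screen a gene set for family members defined by domain architecture.

A heat-shock-factor-style family is defined by joint presence of a
DNA-binding domain (DBD) and an HR-A/B oligomerization region; candidates
with only one of the two are excluded.
"""

from wgdscan.genome_model import DomainHit, GeneModel, assign_ranks, screen_family

genes = assign_ranks(
    [
        GeneModel("Hsf-01", "demo", "chr1", 1_000, 2_000),
        GeneModel("Hsf-02", "demo", "chr1", 50_000, 51_200),
        GeneModel("frag-1", "demo", "chr1", 90_000, 90_600),
        GeneModel("other", "demo", "chr2", 1_000, 2_000),
    ]
)
domains = [
    DomainHit("Hsf-01", "DBD", 10, 105, 210.0),
    DomainHit("Hsf-01", "HR-A/B", 130, 170, 75.0),
    DomainHit("Hsf-02", "DBD", 8, 100, 190.0),
    DomainHit("Hsf-02", "HR-A/B", 125, 168, 80.0),
    DomainHit("frag-1", "DBD", 5, 98, 55.0),  # truncated: no HR-A/B
]

family = screen_family(genes, domains)
print("family members:", family)
# -> ['Hsf-01', 'Hsf-02']; frag-1 is dropped because it lacks the
#    oligomerization region, so it cannot form trimers like a true Hsf.
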
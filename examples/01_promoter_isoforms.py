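"""Group transcripts into promoter-isoforms and classify identifiability.

A gene's transcripts are grouped by their strand-aware transcription
start site (TSS): every transcript sharing a TSS belongs to one
promoter-isoform.  Promoters are ranked 5' -> 3' in transcription
direction (rank 1 is the canonical 5'-most promoter) and classified by
whether their first-intron splice junctions identify them uniquely:

* ``unique``           — junction reads unambiguously quantify it
* ``internal``         — a first-intron edge coincides with an internal
                         intron of a sibling isoform; reads are ambiguous
* ``single_exon_only`` — no junction at all

Run:  python examples/01_promoter_isoforms.py
"""

from promlink.annotation import (
    TranscriptModel,
    build_promoters,
    classify_identifiability,
    promoter_table,
)

# A three-promoter gene on the minus strand: note that the 5'-most
# promoter (rank 1) is the one with the *largest* genomic TSS.
transcripts = [
    TranscriptModel("txA", "GENE1", "chr1", "-",
                    ((1_000, 1_200), (2_000, 2_300), (5_000, 5_200))),
    TranscriptModel("txB", "GENE1", "chr1", "-",
                    ((1_000, 1_200), (2_000, 2_300), (8_000, 8_150))),
    # txC shares txB's TSS -> same promoter
    TranscriptModel("txC", "GENE1", "chr1", "-",
                    ((1_000, 1_200), (3_000, 3_100), (7_900, 8_150))),
    # txD starts inside the gene; its first intron reuses an internal
    # splice edge of txA, so its promoter is not identifiable
    TranscriptModel("txD", "GENE1", "chr1", "-",
                    ((1_000, 1_200), (2_000, 2_150))),
]

promoters = classify_identifiability(build_promoters(transcripts), transcripts)
table = promoter_table(promoters)

print(table.to_string(index=False))
print()
for p in promoters:
    tag = "5' (canonical)" if p.is_five_prime else "non-5'"
    print(f"{p.promoter_id}: rank {p.rank} [{tag}], class={p.promoter_class}, "
          f"members={sorted(p.member_transcripts)}, "
          f"junctions={sorted(p.first_intron_junctions)}")
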
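"""Build a CATG+17 reference tag database from transcripts.

Every CATG site with 17 nt downstream yields one 21-nt reference tag, on both
strands, ranked from the 3' end (rank 1 = the tag complete NlaIII digestion
would produce).  A tag sequence carried by more than one gene is ambiguous
and will be excluded from quantification later.
"""

from dgetag import ambiguity_classify, extract_reference_tags

transcripts = [
    ("MYOD1", "AAACATGTTTTTTTTTTTTTTTTTAACATGCCCCCCCCCCCCCCCCCGG"),
    ("MYF5", "GGGCATGAAAAAAAAAAAAAAAAATT"),
    ("SHARED_A", "TTCATGGGGGGGGGGGGGGGGGAA"),
    ("SHARED_B", "CCCATGGGGGGGGGGGGGGGGGAA"),  # same tag as SHARED_A
    ("NO_SITE", "ACTACTACTACTACTACTACTACTACT"),
]

db = extract_reference_tags(transcripts)
flags, summary = ambiguity_classify(db)

for tag in db.tags:
    if tag.strand == "sense":
        print(f"{tag.gene_id:10s} rank {tag.site_rank}  {tag.sequence}  "
              f"{'unambiguous' if flags[tag.sequence] else 'AMBIGUOUS'}")
print()
for key, value in summary.items():
    print(f"{key:35s} {value}")

# MYOD1 contributes two ranked sense tags (two CATG sites); the tag shared by
# SHARED_A/SHARED_B is flagged ambiguous; NO_SITE is counted as siteless and
# is invisible to the assay.
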
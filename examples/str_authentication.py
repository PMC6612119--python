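"""Authenticate the clonal cell lines against the ATCC reference STR profile.

Builds the GenePrint-10 locus table for the parental MDA-MB-231 line and its
three color-coded clones, then counts, locus by locus, how many reference
alleles each clone shares with the ATCC HTB-26 database entry.
"""

import io

import clonetrace as ct

table = ct.make_str_fixture()
print("STR profile table (alleles per locus):")
print(table.to_string())

buf = io.StringIO()
table.to_csv(buf, sep="\t")
buf.seek(0)
profiles = {p.name: p for p in ct.parse_profiles(buf)}
reference = profiles.pop("ATCC HTB-26")

print("\nmatch against the ATCC HTB-26 reference:")
for name, profile in profiles.items():
    r = ct.match_profiles(profile, reference)
    print(f"  {name}: shared {r.shared} / {r.db_total} database alleles "
          f"-> {r.percent}% match")

print(
    "\nAll lines share 14 of 16 reference alleles (87%, truncated): the two\n"
    "misses are one allele each at D7S820 and vWA, where the clones carry a\n"
    "single allele of the reference pair — consistent with descent from the\n"
    "parental line rather than cross-contamination."
)
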
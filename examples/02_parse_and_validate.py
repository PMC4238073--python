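"""Parse the packaged worked example and round-trip it between dialects.

The bundled description of *Megaselia shadeae* — a Costa Rican
cloud-forest species with a bubbled, pigmented central wing spot — is
the reference transcription of a table-based description.
"""

from megakey import parse_description, validate_description, write_description
from megakey.datasets import shadeae_description

d = shadeae_description()
print("taxon:", d.taxon_name)
print("wing length (mm):", d.value_of("wing_length_mm"))
print("costal index:", d.value_of("costal_index"))
print("costal ratios:", d.value_of("costal_ratios"))
print("posterior setation:", d.value_of("posterior_setation"))
print("remark on R_2+3:", d.character_remarks["r2_3"])
print("general remarks:", d.general_remarks)
print("validation findings:", validate_description(d))  # [] = fully valid
for f in d.parse_warnings:
    print("parse warning:", f.character_id, "-", f.message)

json_text = write_description(d, "json")
round_tripped = parse_description(json_text)
print("JSON round trip preserves every value:", round_tripped == d)
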
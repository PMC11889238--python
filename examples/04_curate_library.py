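"""Read, harmonize and curate an .msp spectral library.

Writes a small synthetic library, corrupts one record with an unsupported
adduct, then runs metadata harmonization (adduct whitelist, collision-energy
normalization to eV, SMILES/InChIKey consistency) and the training filters,
producing a curated library plus an exclusion report.
"""

import tempfile
from pathlib import Path

from bondbreak import make_library, read_msp, write_msp
from bondbreak.msp import Exclusion, harmonize_metadata

workdir = Path(tempfile.mkdtemp())
raw = workdir / "raw.msp"
make_library(8, 2, path=str(raw), seed=12)

# corrupt one record: sodium adduct, which the model does not cover
text = raw.read_text().replace("Precursor_type: [M+H]+", "Precursor_type: [M+Na]+", 1)
raw.write_text(text)

kept, excluded = [], []
for record in read_msp(str(raw)):
    result = harmonize_metadata(record)
    if isinstance(result, Exclusion):
        excluded.append(result)
    else:
        kept.append(result)

curated = workdir / "curated.msp"
write_msp(kept, str(curated))
print(f"read {len(kept) + len(excluded)} records from {raw}")
print(f"kept {len(kept)} after harmonization -> {curated}")
for e in excluded:
    print(f"excluded record {e.record_index} ({e.name}): {e.reason}")
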
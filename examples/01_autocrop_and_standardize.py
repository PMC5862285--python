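"""Standardize a reconstruction: autocrop, bin, compress, write NRRD.

Builds a synthetic embryo scan, removes the empty space around the specimen
with the MIP + Otsu autocrop, halves the resolution by 2x2x2 binning and
writes a bzip2-compressed NRRD. The printed numbers show how much storage
the crop and compression save — the point of the standardization step.
"""

import tempfile
from pathlib import Path

from embryotk import autocrop_volume, bin_volume, phantom_gen, write_nrrd

ph = phantom_gen.make_embryo_phantom(phantom_gen.random_embryo_spec(seed=4))
vol = ph.volume
print(f"original: shape {vol.shape}, {vol.data.nbytes / 1024:.0f} KiB raw")

cropped, box = autocrop_volume(vol, padding=8)
kept = 100 * cropped.data.size / vol.data.size
print(f"auto crop box {box.format()} keeps {kept:.0f}% of the voxels")

binned = bin_volume(cropped, 2)
print(f"binned 2x: shape {binned.shape}, spacing {binned.spacing} um")

with tempfile.TemporaryDirectory() as d:
    path = write_nrrd(binned, Path(d) / "standardized.nrrd", compress=True)
    size = path.stat().st_size
    print(f"bzip2 NRRD: {size / 1024:.0f} KiB on disk "
          f"({binned.data.nbytes / 1024:.0f} KiB uncompressed payload)")
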
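"""Convert BOLD windows to palette images for the image-based regressor.

Renders one synthetic window through the frozen 256-color palette, writes
it as a PNG and shows that the mapping is invertible up to the
quantization step of (max - min) / 255.
"""

import numpy as np
from PIL import Image

import hopfbif as hb
from hopfbif.synthdata import load_palette

conn = hb.random_connectome(10, seed=0)
data = hb.generate_training_set(1, 50, conn, 1.0, hb.SimulationConfig(seed=5))
window = data.windows[0]

img = hb.to_image(window)
print(f"image: {img.pixels.shape[0]} x {img.pixels.shape[1]} pixels, palette {img.palette_id}")
Image.fromarray(img.pixels).save("window.png")
print("wrote window.png (height = regions, width = time steps)")

pal = load_palette().astype(int)
flat = img.pixels.reshape(-1, 3).astype(int)
idx = np.array([np.argmin(((pal - p) ** 2).sum(axis=1)) for p in flat])
recovered = idx.reshape(window.shape) / 255.0 * 2.0 - 1.0
err = np.abs(recovered - np.clip(window, -1, 1)).max()
print(f"max round-trip error: {err:.5f} (quantization step = {2/255:.5f})")
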
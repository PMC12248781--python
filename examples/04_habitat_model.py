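"""Train the bird-habitat MLP and map habitat suitability over the raster.

Every planted tree becomes a training sample (LST at its pixel, cooling
index, shade index, height, diameter) labelled 1 iff its species supports
birds. A 5->16->8->1 ReLU/sigmoid network is trained with Adam (150
epochs, batch 10, 80:20 split), then applied per pixel with mean-filled
non-LST features; pixels above probability 0.5 are hotspots.
"""

import numpy as np

import treegrid as tg

cfg = tg.SynthConfig(seed=3, raster_shape=(48, 48))
db = tg.gen_species_db(cfg)
grid = tg.gen_lst_raster(cfg)
nr, nc = grid.shape
center = grid.pixel_center(nr // 2, nc // 2)
poly = tg.square_polygon(center.latitude, center.longitude, 0.8 * nr * cfg.pixel_size * 111_194.93)
layout = tg.gen_layout(poly, db, n=80, seed=3)

samples = tg.build_training_table(layout, db, grid)
model = tg.train(samples, tg.ModelConfig(seed=3))
last = model.history.iloc[-1]
print(f"samples: {len(samples)} ({sum(s.label for s in samples)} bird-positive)")
print(f"after {model.config.epochs} epochs: train acc {last.train_acc:.3f}, val acc {last.val_acc:.3f}")

probs = np.array([tg.predict_proba(model, s.features()) for s in samples])
roc = tg.roc_auc([s.label for s in samples], probs)
print(f"in-sample AUC: {roc.auc:.3f}  (0.5 = chance, 1.0 = perfect discrimination)")

surface = tg.predict_raster(model, grid)
hotspots = tg.classify_hotspots(surface)
frac = float(np.nanmean(hotspots.values))
print(f"probability surface: {np.nanmin(surface.values):.2f}-{np.nanmax(surface.values):.2f}; "
      f"{frac:.0%} of pixels classed as bird-habitat hotspots (p > 0.5)")
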
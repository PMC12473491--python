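# sesame3d

Organ-level phenotyping of sesame (*Sesamum indicum* L.) plants from dense
3D point clouds.

Plant breeders need per-plant, per-organ measurements — plant height, stem
diameter, leaf length/width/angle/area — at a throughput that rulers and
protractors cannot deliver. Multi-view reconstruction turns a potted plant
into a dense colored point cloud; this package turns that cloud into those
six phenotypic parameters:

1. **Preprocessing** — local-density filtering, excess-green color
   filtering (keep points with ExG = 2G − R − B > 30), statistical outlier
   removal, voxel-grid downsampling; real units enter through a calibration
   cube of known 2 cm edge (`r = H_real / H_reconstructed`).
2. **Semantic segmentation** — CAVF-PointNet++, a hierarchical set
   abstraction / feature propagation network labelling every point as stem,
   petiole or leaf. It augments the plain backbone with a context-anchor
   attention block (CAA) inside each local encoder and trains with the
   varifocal loss `VFL(p, q) = −q log p − (1 − q)^γ log(1 − p)`. Both are
   switchable; disabling them recovers vanilla PointNet++ bit for bit.
3. **Leaf instance segmentation** — where leaves touch, the surface normal
   changes abruptly; the per-point statistic
   `Curvature_i = (1/k) Σ_j ‖n_j − n_i‖` spikes there. Points above a
   curvature threshold (0.2) are removed and DBSCAN (ε = 0.006,
   MinPts = 10) splits the rest into one cluster per leaf.
4. **Trait extraction** — PCA of the stem defines the plant Z axis; height
   is the bounding-box Z extent, stem diameter comes from a least-squares
   circle fit to a slice 2 cm above ground, leaf length from a greedy
   midrib walk between the two farthest leaf points, leaf width from the
   leaf's cross-axis extent, leaf angle from the petiole's principal
   direction against the stem axis, and leaf area from Delaunay
   triangulation in the leaf's principal plane.

Evaluation metrics (OA, mIoU, per-leaf precision/recall/F1, R², RMSE) and a
seeded synthetic-plant generator with analytic ground truth round out the
package, so the whole pipeline is testable end to end without any data
download.

## Worked example

Simulate a 4-leaf plant scene (soil, calibration cube, colored plant),
clean it, cluster the leaves and extract traits:

```bash
$ sesame3d simulate --seed 4 --n-leaves 4 --out scene.ply --truth plant.txt
scene: 74836 points, r=40.0 cm/unit, height=100.0 cm, 4 leaves

$ sesame3d preprocess --in scene.ply --out clean.ply --voxel 0.003
input: 74836 points
density: 71094 points
color: 64207 points
statistical: 51209 points
voxel: 21011 points

$ sesame3d cluster-leaves --in plant.txt --out inst.txt
4 leaf instances, 0 noise points

$ sesame3d traits --in inst.txt --scale 40 --out traits.csv
height 100.0 cm, diameter 9.5 mm, 4 leaves
```

The per-stage counts show the cascade at work: the color filter strips the
soil and cube (they are constructed with ExG ≤ 30), statistical filtering
trims stragglers, and the voxel grid thins the cloud. The trait report:

```
kind,instance,plant_height_cm,stem_diameter_mm,leaf_length_cm,leaf_width_cm,leaf_angle_deg,leaf_area_cm2
plant,,99.9968,9.54256,,,,
leaf,0,,,9.92374,4.78694,50.0048,31.933
leaf,1,,,10.0118,4.77763,50.182,31.9501
leaf,2,,,9.97916,4.77459,50.1481,32.0293
leaf,3,,,9.99994,4.77889,49.9189,31.9745
```

This plant was generated with a true height of 100 cm, stem diameter
9.54 mm, leaf length 10 cm, width 4.8 cm, insertion angle 50° and lamina
area 32.6 cm² — every extracted value lands within a few percent of the
analytic truth.

The same works from Python:

```python
import sesame3d as s3d

spec = s3d.default_plant_spec(seed=4, n_leaves=4)
labeled, truth = s3d.generate_plant(spec)
report = s3d.extract_all_traits(labeled, None, truth.r)
print(report.plant_height_cm, report.stem_diameter_mm)
```

Training and applying the segmentation network (CPU-scale):

```python
from sesame3d.network import TOY_FP_MLPS, TOY_SA_CONFIG
model = s3d.CAVFPointNetSegmenter(
    n_points=512, sa_config=TOY_SA_CONFIG, fp_mlps=TOY_FP_MLPS,
    epochs=50, batch_size=1, lr=0.005, validation_fraction=0.0)
model.fit(clouds, labels)        # lists of (N,6) arrays / (N,) labels
pred = model.predict_one(clouds[0])
```

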
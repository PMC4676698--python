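"""Quantify molecular co-clustering with cross-RDF and cross-Ripley H.

Generates two molecular species co-clustered in the same 50 nm clusters,
computes the pair-correlation function G(r) and Ripley's H(r), and
estimates the mean cluster radius from the H peak two ways.
"""

from miisr import (cluster_radius_lagache, cross_rdf, cross_ripley,
                   default_radii, make_clustered_scene)

scene = make_clustered_scene(extent=5000.0, n_clusters=50,
                             molecules_per_cluster=100, size_jitter=0,
                             cluster_radius=50.0, radius_jitter=0.0,
                             noise_fraction=0.1, n_channels=2, seed=1)
a, b = scene.channel("A"), scene.channel("B")
radii = default_radii(r_max=500.0, dr=10.0)

g = cross_rdf(a, b, region=scene.region, radii=radii, toroidal=True)
k, h, hp = cross_ripley(a, b, region=scene.region, radii=radii,
                        toroidal=True)

print(f"G(r) at 5 nm  = {g.values[0]:.1f}   (cluster interior, >> 1)")
print(f"G(r) at 495 nm = {g.values[-1]:.2f}  (inter-cluster, ~ 1)")
print(f"H peak: H(r_max) = {h.values.max():.0f} at r_max = "
      f"{h.r_max_peak:.0f} nm")
print(f"Lagache radius estimate r_max/1.3 = "
      f"{cluster_radius_lagache(h):.1f} nm (true radius 50 nm)")

# G >> 1 at small r and ~1 at large r quantifies clustering strength;
# the single positive H peak marks the cluster scale, and r_max/1.3
# recovers the generator's 50 nm radius.
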
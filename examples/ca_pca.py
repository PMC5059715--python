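"""Cα principal component analysis with a planted dominant mode.

Generates a trajectory whose first principal mode carries a planted 32% of
the total variance over an isotropic background (emulating a collective
core-vs-dimerization-domain motion on top of thermal noise), writes it to a
multi-MODEL PDB, reads it back and recovers the spectrum.
"""

from cphmc import gen_pca_trajectory, pca_ca, read_pdb, write_pdb

trajectory, truth = gen_pca_trajectory(
    n_atoms=30, mode_variances=(16.0,), n_frames=1200,
    background_variance=0.3914, seed=8,
)
print(f"planted first-mode variance fraction: {truth['expected_fractions'][0]:.3f}")

write_pdb(trajectory, "/tmp/pca_traj.pdb")
frames = read_pdb("/tmp/pca_traj.pdb")
result = pca_ca(frames, align=False)
print(f"recovered from PDB round trip:        {result.variance_fractions[0]:.3f}")
print(f"next four fractions: "
      + " ".join(f"{f:.3f}" for f in result.variance_fractions[1:5]))
print("(one collective mode stands far above the isotropic background, "
      "as in a dominant rocking motion)")
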
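"""Build a small training corpus and fit the neural surrogate.

Each corpus row draws the 25 varied patient/wound parameters uniformly
(rejecting draws that violate the stability condition
k_c < delta_c * rho_bar * a_c_II), simulates the 365-day RSA course, and
the 25 -> 100 -> 100 -> 365 network learns the mapping.  A few hundred
samples already give a usable fit; thousands give R² > 0.99.
"""

import scarnet as sn

N = 300          # increase toward a few thousand for production accuracy
corpus = sn.generate_corpus(N, master_seed=0, n_nodes=101, progress=True)
split = sn.split_and_scale(corpus, train_fraction=0.8, n_folds=10, seed=0)

model = sn.build_network(seed=0, scaler=split.scaler,
                         feature_names=corpus.feature_names)
sn.train(model, split.X_train, split.Y_train,
         config=sn.TrainingConfig())          # Adamax, lr 0.015, early stop

pred = model.forward(split.X_test)
print(f"test R^2     : {sn.r_squared(split.Y_test, pred):.4f}")
print(f"test aRRMSE  : {sn.arrmse(split.Y_test, pred):.4f}  (< 0.1 is "
      "conventionally 'excellent')")
print(f"test aRelErr : {100 * sn.arelerr(split.Y_test, pred):.2f}%")

model.save("surrogate.npz")
print(f"saved {model.n_parameters}-parameter surrogate to surrogate.npz")
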
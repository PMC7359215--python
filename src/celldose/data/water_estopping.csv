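# Collision stopping power of electrons in liquid water (unit density).
# Computed from the low-energy-corrected Bethe parameterization
# S(E) = 785 (rho Z / A E) ln[1.166 (E + 0.85 J)/J] eV/Angstrom,
# Z=10, A=18.0153, J=75 eV. Columns: energy_keV, stopping_keV_per_um.
1.000000e-02,5.959712e+01
1.042308e-02,5.956942e+01
1.086405e-02,5.952895e+01
1.132369e-02,5.947583e+01
1.180277e-02,5.941013e+01
1.230211e-02,5.933195e+01
1.282259e-02,5.924135e+01
1.336508e-02,5.913839e+01
1.393053e-02,5.902314e+01
1.451989e-02,5.889565e+01
1.513420e-02,5.875596e+01
1.577449e-02,5.860412e+01
1.644187e-02,5.844016e+01
1.713749e-02,5.826411e+01
1.786254e-02,5.807601e+01
1.861826e-02,5.787588e+01
1.940596e-02,5.766377e+01
2.022698e-02,5.743970e+01
2.108273e-02,5.720370e+01
2.197470e-02,5.695580e+01
2.290440e-02,5.669606e+01
2.387343e-02,5.642450e+01
2.488346e-02,5.614117e+01
2.593622e-02,5.584613e+01
2.703352e-02,5.553943e+01
2.817725e-02,5.522114e+01
2.936936e-02,5.489134e+01
3.061191e-02,5.455009e+01
3.190703e-02,5.419750e+01
3.325694e-02,5.383367e+01
3.466397e-02,5.345871e+01
3.613052e-02,5.307273e+01
3.765912e-02,5.267588e+01
3.925239e-02,5.226829e+01
4.091306e-02,5.185014e+01
4.264400e-02,5.142159e+01
4.444817e-02,5.098283e+01
4.632867e-02,5.053405e+01
4.828873e-02,5.007546e+01
5.033171e-02,4.960730e+01
5.246113e-02,4.912980e+01
5.468064e-02,4.864321e+01
5.699405e-02,4.814780e+01
5.940534e-02,4.764385e+01
6.191864e-02,4.713166e+01
6.453828e-02,4.661152e+01
6.726874e-02,4.608375e+01
7.011473e-02,4.554869e+01
7.308112e-02,4.500668e+01
7.617301e-02,4.445806e+01
7.939572e-02,4.390320e+01
8.275477e-02,4.334246e+01
8.625593e-02,4.277623e+01
8.990522e-02,4.220489e+01
9.370890e-02,4.162884e+01
9.767351e-02,4.104847e+01
1.018058e-01,4.046419e+01
1.061130e-01,3.987640e+01
1.106024e-01,3.928553e+01
1.152817e-01,3.869197e+01
1.201590e-01,3.809615e+01
1.252427e-01,3.749848e+01
1.305414e-01,3.689937e+01
1.360643e-01,3.629924e+01
1.418209e-01,3.569850e+01
1.478210e-01,3.509754e+01
1.540750e-01,3.449678e+01
1.605935e-01,3.389661e+01
1.673879e-01,3.329741e+01
1.744697e-01,3.269958e+01
1.818511e-01,3.210348e+01
1.895448e-01,3.150948e+01
1.975640e-01,3.091795e+01
2.059225e-01,3.032922e+01
2.146346e-01,2.974364e+01
2.237153e-01,2.916153e+01
2.331801e-01,2.858321e+01
2.430454e-01,2.800899e+01
2.533281e-01,2.743914e+01
2.640459e-01,2.687397e+01
2.752170e-01,2.631372e+01
2.868608e-01,2.575866e+01
2.989973e-01,2.520903e+01
3.116471e-01,2.466506e+01
3.248322e-01,2.412696e+01
3.385751e-01,2.359494e+01
3.528994e-01,2.306918e+01
3.678298e-01,2.254987e+01
3.833918e-01,2.203716e+01
3.996122e-01,2.153121e+01
4.165189e-01,2.103216e+01
4.341409e-01,2.054013e+01
4.525084e-01,2.005524e+01
4.716529e-01,1.957759e+01
4.916075e-01,1.910727e+01
5.124063e-01,1.864436e+01
5.340850e-01,1.818892e+01
5.566809e-01,1.774102e+01
5.802328e-01,1.730070e+01
6.047811e-01,1.686800e+01
6.303680e-01,1.644295e+01
6.570374e-01,1.602556e+01
6.848351e-01,1.561585e+01
7.138089e-01,1.521381e+01
7.440085e-01,1.481943e+01
7.754858e-01,1.443271e+01
8.082948e-01,1.405361e+01
8.424919e-01,1.368212e+01
8.781358e-01,1.331818e+01
9.152877e-01,1.296176e+01
9.540114e-01,1.261282e+01
9.943734e-01,1.227128e+01
1.036443e+00,1.193710e+01
1.080293e+00,1.161021e+01
1.125997e+00,1.129054e+01
1.173636e+00,1.097801e+01
1.223289e+00,1.067256e+01
1.275044e+00,1.037408e+01
1.328988e+00,1.008251e+01
1.385214e+00,9.797758e+00
1.443820e+00,9.519725e+00
1.504904e+00,9.248322e+00
1.568573e+00,8.983452e+00
1.634936e+00,8.725020e+00
1.704107e+00,8.472925e+00
1.776203e+00,8.227066e+00
1.851350e+00,7.987342e+00
1.929677e+00,7.753649e+00
2.011317e+00,7.525882e+00
2.096411e+00,7.303938e+00
2.185105e+00,7.087709e+00
2.277552e+00,6.877091e+00
2.373910e+00,6.671977e+00
2.474345e+00,6.472261e+00
2.579029e+00,6.277836e+00
2.688141e+00,6.088597e+00
2.801870e+00,5.904437e+00
2.920411e+00,5.725253e+00
3.043967e+00,5.550937e+00
3.172750e+00,5.381388e+00
3.306982e+00,5.216500e+00
3.446892e+00,5.056173e+00
3.592723e+00,4.900303e+00
3.744722e+00,4.748791e+00
3.903153e+00,4.601537e+00
4.068286e+00,4.458441e+00
4.240406e+00,4.319408e+00
4.419808e+00,4.184341e+00
4.606800e+00,4.053145e+00
4.801703e+00,3.925726e+00
5.004852e+00,3.801993e+00
5.216595e+00,3.681854e+00
5.437297e+00,3.565221e+00
5.667337e+00,3.452005e+00
5.907109e+00,3.342120e+00
6.157025e+00,3.235481e+00
6.417515e+00,3.132004e+00
6.689025e+00,3.031608e+00
6.972022e+00,2.934212e+00
7.266992e+00,2.839737e+00
7.574442e+00,2.748106e+00
7.894899e+00,2.659242e+00
8.228914e+00,2.573072e+00
8.577060e+00,2.489523e+00
8.939936e+00,2.408523e+00
9.318164e+00,2.330003e+00
9.712394e+00,2.253894e+00
1.012330e+01,2.180129e+00
1.055160e+01,2.108644e+00
1.099801e+01,2.039374e+00
1.146331e+01,1.972257e+00
1.194830e+01,1.907232e+00
1.245380e+01,1.844240e+00
1.298069e+01,1.783222e+00
1.352988e+01,1.724122e+00
1.410229e+01,1.666883e+00
1.469893e+01,1.611454e+00
1.532081e+01,1.557779e+00
1.596899e+01,1.505809e+00
1.664461e+01,1.455494e+00
1.734880e+01,1.406783e+00
1.808279e+01,1.359631e+00
1.884783e+01,1.313990e+00
1.964524e+01,1.269815e+00
2.047638e+01,1.227062e+00
2.134269e+01,1.185690e+00
2.224565e+01,1.145655e+00
2.318681e+01,1.106918e+00
2.416779e+01,1.069439e+00
2.519028e+01,1.033179e+00
2.625602e+01,9.981016e-01
2.736685e+01,9.641703e-01
2.852468e+01,9.313497e-01
2.973149e+01,8.996056e-01
3.098936e+01,8.689045e-01
3.230045e+01,8.392140e-01
3.366701e+01,8.105027e-01
3.509138e+01,7.827400e-01
3.657602e+01,7.558960e-01
3.812346e+01,7.299420e-01
3.973638e+01,7.048498e-01
4.141753e+01,6.805923e-01
4.316981e+01,6.571430e-01
4.499623e+01,6.344763e-01
4.689991e+01,6.125672e-01
4.888414e+01,5.913915e-01
5.095232e+01,5.709258e-01
5.310799e+01,5.511474e-01
5.535487e+01,5.320341e-01
5.769680e+01,5.135646e-01
6.013782e+01,4.957179e-01
6.268211e+01,4.784741e-01
6.533405e+01,4.618135e-01
6.809818e+01,4.457172e-01
7.097926e+01,4.301669e-01
7.398223e+01,4.151447e-01
7.711224e+01,4.006333e-01
8.037469e+01,3.866161e-01
8.377515e+01,3.730768e-01
8.731949e+01,3.599997e-01
9.101377e+01,3.473696e-01
9.486435e+01,3.351718e-01
9.887784e+01,3.233919e-01
1.030611e+02,3.120161e-01
1.074214e+02,3.010311e-01
1.119662e+02,2.904238e-01
1.167032e+02,2.801817e-01
1.216406e+02,2.702926e-01
1.267870e+02,2.607447e-01
1.321510e+02,2.515266e-01
1.377420e+02,2.426272e-01
1.435696e+02,2.340360e-01
1.496437e+02,2.257424e-01
1.559748e+02,2.177366e-01
1.625737e+02,2.100087e-01
1.694518e+02,2.025495e-01
1.766209e+02,1.953499e-01
1.840934e+02,1.884010e-01
1.918819e+02,1.816944e-01
2.000000e+02,1.752219e-01
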
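{"state": [-87.84379450714611, 6.371181446692757, 6.371237858239262, 144.58992584837048, 144.58990936157713, 7.225251858767761e-05, 7.086915925115377e-05, 1.3332666600045309, 1.3333907381453172, 0.0031349132514895237, 0.007461817550201586, 0.6926041768477416, 0.6926040348735311, 0.6926031631436509, 0.44857961454202383, 0.6926025267000826, 0.0001940009763609951, 0.5076865398558934, 0.3024093253829744, 0.0010118194227091246, 0.9995417252571863, 0.8674784486997936, 0.0005155520209285507, 0.9995417253220035, 0.9011150726167496, 2.429908458167608e-09, 0.999999990477798, 0.9681487581671671, 0.9999999904777985, 0.9999999738647444, 0.9999999904026718, 0.9999999904777713, 0.999999990477773, 0.0013696969692098089, 8.20209397374806e-06, 0.16652028075080436, 0.14260401628322555, 0.0001962304980010567, 0.9968006785282201, 1.259811683721691e-07, 1.5747448272408778e-07], "stim_amplitude": -320.0, "key": "d2fe1be93918f90c", "bcl": 2000.0, "n_beats": 1000}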
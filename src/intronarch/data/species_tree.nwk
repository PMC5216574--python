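(Aq,(Ta,((Hm,Nv)Cnidaria,((((Ce,Cr)Nematoda,(Is,(Dpu,(Dm,Tc)Insecta)Pancrustacea)Arthropoda)Ecdysozoa,((Ob,(Cg,Lg))Mollusca,(Ct,Hr)Annelida)Lophotrochozoa)Protostomia,((Sk,Spu)Ambulacraria,(Bf,(Ci,(Pm1,(Cmi,((Dr,(Gm1,(Xm1,Tr1)))Actinopterygii,(Xt,((Oa,(Dn,(Clf,(Hs,Mm))))Mammalia,(Ac,(Ps,(Gg,Fa)))Sauropsida)Amniota)Tetrapoda)Osteichthyes)Gnathostomata)Vertebrata)Olfactores)Chordata)Deuterostomia)Bilateria)Planulozoa)Parahoxozoa)Metazoa;
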
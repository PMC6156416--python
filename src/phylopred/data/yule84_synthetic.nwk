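(((((((t1:0.6945626278,(t2:0.3142269712,t3:0.3142269712):0.3803356566):0.6791918776,((t4:0.1997563098,(t5:0.04287870842,t6:0.04287870842):0.1568776014):0.6089627337,((t7:0.4457742335,t8:0.4457742335):0.2350740754,t9:0.6808483089):0.1278707346):0.565035462):0.6287311681,t10:2.002485674):0.1279135681,((t11:0.8487567291,(t12:0.1370262348,t13:0.1370262348):0.7117304943):0.1644760427,(t14:0.6479329447,t15:0.6479329447):0.3652998271):1.11716647):0.05519195007,(((t16:0.06437448236,t17:0.06437448236):0.3756036991,(t18:0.1049066191,t19:0.1049066191):0.3350715624):0.08084100153,t20:0.520819183):1.664772009):0.1865081958,((t21:0.4837343713,(t22:0.2814418001,t23:0.2814418001):0.2022925712):1.128465555,((((t24:0.06151580748,t25:0.06151580748):0.9619744265,((t26:0.7655507389,((t27:0.4056702427,(t28:0.2986959454,t29:0.2986959454):0.1069742973):0.04705990688,t30:0.4527301496):0.3128205894):0.09032389449,t31:0.8558746334):0.1676156005):0.1792270876,(t32:0.2658394961,t33:0.2658394961):0.9368778254):0.06407672802,((t34:0.01285997718,t35:0.01285997718):0.932316879,(t36:0.1999821551,t37:0.1999821551):0.7451947011):0.3216171935):0.3454058765):0.7598994615):2.38417425,((((t38:1.834520644,((t39:1.159770364,((t40:0.4316367875,t41:0.4316367875):0.2766396536,t42:0.7082764411):0.4514939231):0.4010033183,(t43:1.339519104,t44:1.339519104):0.2212545788):0.2737469612):0.548016257,(((t45:0.523444854,((t46:0.2409105738,t47:0.2409105738):0.2812412012,t48:0.522151775):0.001293078989):0.07354174221,t49:0.5969865962):1.515162424,(t50:0.3926794036,t51:0.3926794036):1.719469617):0.2703878805):0.6000737996,(((t52:1.440608072,t53:1.440608072):0.13481701,(t54:0.5023757159,(t55:0.1045291737,t56:0.1045291737):0.3978465421):1.073049367):0.09415485767,t57:1.66957994):1.31303076):1.404204678,((t58:0.2275761957,(t59:0.1944642133,t60:0.1944642133):0.03311198235):2.815734623,((((t61:0.9271778709,(t62:0.02183217114,t63:0.02183217114):0.9053456998):1.242608513,((t64:0.007963536503,t65:0.007963536503):1.879414762,(t66:1.284929012,((t67:0.09775302288,(t68:0.09350498733,t69:0.09350498733):0.004248035545):0.09144151511,t70:0.189194538):1.095734474):0.6024492864):0.2824080849):0.0916931547,(t71:0.1456063472,t72:0.1456063472):2.115873191):0.2307362445,(((t73:0.6187142548,((t74:0.5769675817,((t75:0.4155278226,t76:0.4155278226):0.02702377855,t77:0.4425516012):0.1344159806):0.003295609496,(t78:0.1064654936,t79:0.1064654936):0.4737976977):0.03845106354):0.5196577517,((t80:0.03341365633,t81:0.03341365633):0.8902020911,t82:0.9236157475):0.214756259):1.32806556,(t83:0.5367682439,t84:0.5367682439):1.929669323):0.02577821599):0.5510950361):1.343504559):0.3694582595);
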
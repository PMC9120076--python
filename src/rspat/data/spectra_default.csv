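wavelength_nm,HbO2,HbR,BphP1_Pfr,BphP1_Pr
600,3200.0,14680.0,17.5,4614.1
605,2500.0,13640.0,29.8,6670.9
610,1800.0,12600.0,49.8,9412.1
615,1450.0,11700.0,81.9,12959.4
620,1100.0,10800.0,132.3,17413.3
625,950.0,9900.0,210.1,22833.5
630,800.0,9000.0,327.8,29218.7
635,725.0,8175.0,502.8,36487.8
640,650.0,7350.0,757.9,44466.3
645,605.0,6555.0,1122.7,52882.4
650,560.0,5760.0,1634.7,61374.7
655,520.0,5180.0,2339.2,69512.7
660,480.0,4600.0,3290.0,76830.9
665,450.0,4105.0,4547.8,82871.4
670,420.0,3610.0,6178.6,87231.0
675,400.0,3230.0,8250.0,89605.4
680,380.0,2850.0,10826.8,89824.4
685,365.0,2580.0,13964.6,87872.2
690,350.0,2310.0,17702.7,83889.2
695,350.0,2150.0,22056.2,78155.2
700,350.0,1990.0,27008.6,71056.9
705,357.5,1890.0,32505.3,63045.2
710,365.0,1790.0,38449.3,54587.8
715,377.5,1740.0,44699.5,46124.9
720,390.0,1690.0,51073.9,38034.0
725,410.0,1665.0,57355.6,30606.0
730,430.0,1640.0,63304.4,24034.7
735,445.0,1650.0,68670.9,18419.0
740,460.0,1660.0,73213.8,13775.0
745,490.0,1690.0,76717.4,10053.4
750,520.0,1720.0,79009.0,7160.4
755,555.0,1695.0,79972.3,4976.8
760,590.0,1670.0,79558.0,3375.7
765,620.0,1560.0,77787.4,2234.5
770,650.0,1450.0,74750.8,1443.4
775,680.0,1335.0,70599.8,909.9
780,710.0,1220.0,65534.8,559.7
785,725.0,1110.0,59789.0,336.0
790,740.0,1000.0,53610.8,196.9
795,770.0,940.0,47245.8,112.6
800,800.0,880.0,40921.9,62.8
805,832.5,850.0,34836.1,34.2
810,865.0,820.0,29146.4,18.2
815,897.5,800.0,23967.4,9.4
820,930.0,780.0,19370.4,4.8
825,952.5,770.0,15386.4,2.4
830,975.0,760.0,12012.0,1.1
835,992.5,750.0,9216.7,0.5
840,1010.0,740.0,6950.5,0.2
845,1035.0,735.0,5151.6,0.1
850,1060.0,730.0,3752.7,0.0
855,1075.0,727.5,2686.7,0.0
860,1090.0,725.0,1890.6,0.0
865,1110.0,722.5,1307.5,0.0
870,1130.0,720.0,888.7,0.0
875,1145.0,720.0,593.7,0.0
880,1160.0,720.0,389.8,0.0
885,1175.0,721.0,251.6,0.0
890,1190.0,722.0,159.5,0.0
895,1195.0,723.5,99.5,0.0
900,1200.0,725.0,60.9,0.0
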